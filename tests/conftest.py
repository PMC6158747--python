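"""Shared fixtures: small deterministic scenes and an independent
brute-force ensemble oracle (implemented from the model definition, not
via the package's enumeration machinery)."""

from __future__ import annotations

import math

import numpy as np
import pytest

from electrofold.structures import ContactMap
from electrofold.synthetic import ToySceneSpec, make_scene

R_J = 8.314


@pytest.fixture(scope="session")
def small_spec() -> ToySceneSpec:
    """A 28-residue two-helix toy scene, sized for fast scan tests."""
    return ToySceneSpec(
        n_res=28,
        helix_layout=((3, 12), (17, 26)),
        charge_pattern={5: +1, 8: +1, 11: +1, 20: -1},
        binding_face=(5, 8, 11),
        dna_n_bp=10,
    )


@pytest.fixture(scope="session")
def small_scene(small_spec):
    return make_scene(small_spec)


@pytest.fixture(scope="session")
def default_scene():
    return make_scene()


def brute_force_ensemble(contacts: ContactMap, electro_kj: dict, params,
                         T: float, field_J: np.ndarray | None = None,
                         allowed_islands: int | None = None):
    """Direct 2^N evaluation of the ensemble from the model definition.

    A contact (i, j) contributes when residues i..j are all native;
    free energy = contacts + electrostatics - T*m*dS_conf + field.
    Returns (log_Z, residue_prob, logw_by_n) with logw_by_n the
    per-reaction-coordinate log weight sums.
    """
    N = contacts.n_residues
    if field_J is None:
        field_J = np.zeros(N)
    u = params.xi + params.dCp_cont * (
        (T - params.T_ref) - T * math.log(T / params.T_ref)
    )
    logws, masks = [], []
    for bits in range(2 ** N):
        mask = np.array([(bits >> k) & 1 for k in range(N)], dtype=bool)
        islands = int(np.sum(np.diff(np.concatenate([[0], mask.view(np.int8),
                                                     [0]])) == 1))
        if allowed_islands is not None and islands > allowed_islands:
            continue
        g = 0.0
        for (i, j), c in contacts.pairs.items():
            if mask[i - 1:j].all():
                g += c * u
        for (i, j), e in electro_kj.items():
            if mask[i - 1:j].all():
                g += 1000.0 * e
        g -= T * int(mask.sum()) * params.dS_conf
        g += float(field_J[mask].sum())
        logws.append(-g / (R_J * T))
        masks.append(mask)
    logws = np.array(logws)
    masks = np.array(masks)
    shift = logws.max()
    w = np.exp(logws - shift)
    Z = w.sum()
    log_Z = shift + math.log(Z)
    residue_prob = (w[:, None] * masks).sum(axis=0) / Z
    m = masks.sum(axis=1)
    logw_by_n = np.full(N + 1, -np.inf)
    for n in range(N + 1):
        sel = m == n
        if np.any(sel):
            logw_by_n[n] = shift + math.log(w[sel].sum())
    return log_Z, residue_prob, logw_by_n


def random_contact_system(N: int, seed: int, charge_frac: float = 0.4):
    """A random small contact map + electro matrix + field for oracle tests."""
    rng = np.random.default_rng(seed)
    pairs = {}
    for i in range(1, N + 1):
        for j in range(i + 2, N + 1):
            if rng.random() < 0.45:
                pairs[(i, j)] = int(rng.integers(1, 6))
    if not pairs:
        pairs[(1, N)] = 2
    cm = ContactMap(pairs, cutoff=5.0, min_sequence_separation=2, n_residues=N)
    electro = {}
    for i in range(1, N + 1):
        for j in range(i + 1, N + 1):
            if rng.random() < charge_frac:
                electro[(i, j)] = float(rng.normal(0.0, 2.0))
    field = rng.normal(0.0, 1500.0, N)
    return cm, electro, field
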