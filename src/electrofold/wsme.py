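"""Ising-like (Wako-Saito-Munoz-Eaton) folding ensemble.

Each residue is native (1) or unfolded (0).  A native contact between
residues i and j contributes only when every residue i..j is native (the
single/double-island structure of the allowed microstates makes this the
"both ends in the same folded stretch" rule).  Microstate free energy:

    dG = sum_alive c_ij * [xi + dCp*((T - Tref) - T*ln(T/Tref))]
       + sum_alive E_elec(i,j)  -  T * m * dS_conf
       + sum_{j folded} g_j                       (optional DNA field)

with c_ij the heavy-atom contact count, m the number of native residues,
dS_conf < 0 the per-residue conformational entropy, and g_j a
per-residue free-energy field (J/mol) that re-weights every microstate by
exp(-g_j rho_j / RT).  The fully unfolded state is the reference
(weight 1), so F(0) = 0 at all temperatures.

Production runs truncate the state space to microstates with at most two
contiguous folded stretches (single + double sequence approximation);
full 2^N enumeration is retained for small N as an exact oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .constants import R_J
from .electrostatics import PairEnergyMatrix
from .structures import ContactMap

NEG_INF = -np.inf


@dataclass
class WSMEParameters:
    """Energy scales of the ensemble model (J, mol, K).

    Defaults are the parameterization that reproduces the apo melting
    behavior of a small helical DNA-binding domain: xi (mean interaction
    energy per heavy-atom native contact) = -217.1 J/mol, dS_conf
    (entropic cost of fixing a residue) = -33.31 J/mol/K, dCp_cont
    (temperature-independent heat capacity per native contact)
    = -2.33 J/mol/K, with a solvation reference temperature of 385 K.
    """

    xi: float = -217.1
    dS_conf: float = -33.31
    dCp_cont: float = -2.33
    T_ref: float = 385.0
    eps_prot: float = 29.0
    gas_constant: float = R_J

    def __post_init__(self) -> None:
        if self.dS_conf >= 0:
            raise ValueError("dS_conf must be negative (entropic cost)")
        if self.T_ref <= 0:
            raise ValueError("T_ref must be positive")

    def contact_energy(self, T: float) -> float:
        """Per-contact interaction + solvation free energy at T, J/mol."""
        return self.xi + self.dCp_cont * ((T - self.T_ref) - T * math.log(T / self.T_ref))

    def contact_enthalpy(self, T: float) -> float:
        """Per-contact enthalpic part of :meth:`contact_energy`, J/mol."""
        return self.xi + self.dCp_cont * (T - self.T_ref)


@dataclass(frozen=True)
class Microstate:
    """Disjoint, non-adjacent folded stretches [start, end] (1-based)."""

    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = -10
        for a, b in self.segments:
            if b < a:
                raise ValueError(f"segment ({a}, {b}) reversed")
            if a <= prev_end + 1:
                raise ValueError("segments must be sorted with gaps >= 1")
            prev_end = b
        object.__setattr__(
            self, "n_folded", sum(b - a + 1 for a, b in self.segments)
        )

    n_folded: int = field(init=False, default=0)

    def folded_mask(self, N: int) -> np.ndarray:
        mask = np.zeros(N, dtype=bool)
        for a, b in self.segments:
            mask[a - 1:b] = True
        return mask


def enumerate_microstates(N: int, max_islands: int | None = 2) -> Iterator[Microstate]:
    """Yield the unfolded state plus all microstates with at most
    ``max_islands`` folded stretches; ``max_islands=None`` enumerates the
    full 2^N space (refused for N > 25)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if max_islands is None:
        if N > 25:
            raise ValueError("full enumeration refused for N > 25")
        for bits in range(2**N):
            yield Microstate(_segments_from_bits(bits, N))
        return
    if max_islands not in (1, 2):
        raise ValueError("max_islands must be 1, 2 or None (full enumeration)")
    yield Microstate(())
    for a1 in range(1, N + 1):
        for b1 in range(a1, N + 1):
            yield Microstate(((a1, b1),))
            if max_islands >= 2:
                for a2 in range(b1 + 2, N + 1):
                    for b2 in range(a2, N + 1):
                        yield Microstate(((a1, b1), (a2, b2)))


def _segments_from_bits(bits: int, N: int) -> tuple[tuple[int, int], ...]:
    segs = []
    j = 1
    while j <= N:
        if bits >> (j - 1) & 1:
            start = j
            while j <= N and bits >> (j - 1) & 1:
                j += 1
            segs.append((start, j - 1))
        else:
            j += 1
    return tuple(segs)


def _field_array(field_like, N: int) -> np.ndarray:
    """Per-residue free energies g_j in J/mol as a length-N array."""
    if field_like is None:
        return np.zeros(N)
    if hasattr(field_like, "as_array"):
        return np.asarray(field_like.as_array(N), dtype=float)
    if isinstance(field_like, Mapping):
        out = np.zeros(N)
        for j, g in field_like.items():
            out[int(j) - 1] = float(g)
        return out
    arr = np.asarray(field_like, dtype=float)
    if arr.shape != (N,):
        raise ValueError(f"field must have length {N}")
    return arr


def microstate_free_energy(state: Microstate, contacts: ContactMap,
                           electro: PairEnergyMatrix | None,
                           params: WSMEParameters, T: float,
                           field=None) -> float:
    """Free energy of one microstate relative to the unfolded state, J/mol."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    N = contacts.n_residues
    mask = state.folded_mask(N)
    u = params.contact_energy(T)
    g = 0.0
    for (i, j), c in contacts.pairs.items():
        if mask[i - 1:j].all():
            g += c * u
    if electro is not None:
        for (i, j), e in electro.entries.items():
            if mask[i - 1:j].all():
                g += 1000.0 * e
    g -= T * state.n_folded * params.dS_conf
    if field is not None:
        g += float(_field_array(field, N)[mask].sum())
    return g


@dataclass
class EnsembleSummary:
    """Equilibrium observables of the ensemble at one temperature."""

    temperature: float
    log_Z: float
    residue_prob: np.ndarray  # <rho_j>, per residue
    mean_PF: float  # unweighted mean of <rho_j>
    mean_H: float  # kJ/mol
    profile: np.ndarray | None = None  # F(n), kJ/mol, n = 0..N

    @property
    def Z(self) -> float:
        return float(np.exp(self.log_Z))


class WSMEEnsemble:
    """Reusable engine: precomputes interval sums once, then evaluates
    observables at any temperature (and under any per-residue field)."""

    def __init__(self, contacts: ContactMap,
                 electro: PairEnergyMatrix | None = None,
                 params: WSMEParameters | None = None,
                 field=None, max_islands: int = 2,
                 electro_pairs: str = "all"):
        if max_islands not in (1, 2):
            raise ValueError("engine supports max_islands 1 or 2; use "
                             "ensemble_summary(..., max_islands=None) for the "
                             "exact small-N path")
        self.params = params or WSMEParameters()
        self.contacts = contacts
        self.max_islands = max_islands
        N = self.N = contacts.n_residues

        ncon = np.zeros((N, N))
        for (i, j), c in contacts.pairs.items():
            if not (1 <= i < j <= N):
                raise ValueError(f"contact {(i, j)} outside 1..{N}")
            ncon[i - 1, j - 1] = c
        eel = np.zeros((N, N))
        if electro is not None:
            for (i, j), e in electro.entries.items():
                if not (1 <= i < j <= N):
                    raise ValueError(f"electro pair {(i, j)} outside 1..{N}")
                if electro_pairs == "contacts" and (i, j) not in contacts.pairs:
                    continue
                eel[i - 1, j - 1] = 1000.0 * e  # kJ -> J

        self._ncon_int = _interval_sums(ncon)
        self._eel_int = _interval_sums(eel)
        self.ia, self.ib = np.triu_indices(N)
        self.length = self.ib - self.ia + 1
        self._ncon_I = self._ncon_int[self.ia, self.ib]
        self._eel_I = self._eel_int[self.ia, self.ib]
        self.set_field(field)

    def set_field(self, field) -> None:
        g = _field_array(field, self.N)
        cs = np.concatenate([[0.0], np.cumsum(g)])
        self._fld_I = cs[self.ib + 1] - cs[self.ia]

    def with_field(self, field) -> "WSMEEnsemble":
        import copy

        eng = copy.copy(self)
        eng.set_field(field)
        return eng

    # -- core evaluation ---------------------------------------------------

    def _island_logw(self, T: float) -> np.ndarray:
        p = self.params
        dG = (self._ncon_I * p.contact_energy(T) + self._eel_I + self._fld_I
              - T * self.length * p.dS_conf)
        return -dG / (p.gas_constant * T)

    def summary(self, T: float, compute_profile: bool = True) -> EnsembleSummary:
        if T <= 0:
            raise ValueError("temperature must be positive")
        N, ia, ib = self.N, self.ia, self.ib
        logw = self._island_logw(T)

        # per-start and per-end aggregates, then suffix/prefix accumulation
        by_start = np.full(N, NEG_INF)
        np.logaddexp.at(by_start, ia, logw)
        by_end = np.full(N, NEG_INF)
        np.logaddexp.at(by_end, ib, logw)
        suf = np.full(N + 3, NEG_INF)  # suf[s] = lse over islands starting >= s
        suf[N - 1] = by_start[N - 1]
        for s in range(N - 2, -1, -1):
            suf[s] = np.logaddexp(suf[s + 1], by_start[s])
        pref = np.full(N + 1, NEG_INF)  # pref[e] = lse over islands ending <= e (0-based e)
        pref[0] = by_end[0]
        for e in range(1, N):
            pref[e] = np.logaddexp(pref[e - 1], by_end[e])

        if self.max_islands >= 2:
            right = suf[np.minimum(ib + 2, N + 2)]
            left = np.where(ia >= 2, pref[np.maximum(ia - 2, 0)], NEG_INF)
        else:
            right = np.full_like(logw, NEG_INF)
            left = np.full_like(logw, NEG_INF)

        pair_terms = logw + right  # each unordered pair counted once
        log_Z = logsumexp(np.concatenate([[0.0], logw, pair_terms]))

        # occupancy weight of island I over all states containing it
        occ = logw + np.logaddexp(0.0, np.logaddexp(right, left))

        num = np.full(N, NEG_INF)
        for k in range(len(logw)):
            s = slice(ia[k], ib[k] + 1)
            num[s] = np.logaddexp(num[s], occ[k])
        residue_prob = np.exp(num - log_Z)

        p = self.params
        H_I = (self._ncon_I * p.contact_enthalpy(T) + self._eel_I + self._fld_I)
        mean_H = float(np.sum(H_I * np.exp(occ - log_Z))) / 1000.0

        profile = None
        if compute_profile:
            blog = np.full(N + 1, NEG_INF)
            blog[0] = 0.0
            np.logaddexp.at(blog, self.length, logw)
            if self.max_islands >= 2:
                # suffix-by-length table: M[s, l] = lse over islands with
                # start >= s and length l
                M = np.full((N + 3, N + 1), NEG_INF)
                M[ia, self.length] = logw
                for s in range(N - 1, -1, -1):
                    M[s] = np.logaddexp(M[s], M[s + 1])
                lens = np.arange(1, N + 1)
                for k in range(len(logw)):
                    s2 = ib[k] + 2
                    if s2 > N - 1:
                        continue
                    vec = logw[k] + M[s2, 1:]
                    tgt = self.length[k] + lens
                    ok = tgt <= N
                    np.logaddexp.at(blog, tgt[ok], vec[ok])
            profile = -p.gas_constant * T * blog / 1000.0
            profile[0] = 0.0

        return EnsembleSummary(temperature=T, log_Z=float(log_Z),
                               residue_prob=residue_prob,
                               mean_PF=float(residue_prob.mean()),
                               mean_H=mean_H, profile=profile)

    def folding_curve(self, T_grid: Sequence[float]) -> np.ndarray:
        return np.array(
            [self.summary(T, compute_profile=False).mean_PF for T in T_grid]
        )

    def enthalpy_curve(self, T_grid: Sequence[float]) -> np.ndarray:
        return np.array(
            [self.summary(T, compute_profile=False).mean_H for T in T_grid]
        )


def _interval_sums(M: np.ndarray) -> np.ndarray:
    """S[a, b] = sum of M[i, j] over a <= i < j <= b (upper-tri input)."""
    N = M.shape[0]
    out = np.zeros((N, N))
    # colcum[a, j] = sum_{i >= a, i < j} M[i, j]
    colcum = np.flip(np.cumsum(np.flip(np.triu(M, 1), axis=0), axis=0), axis=0)
    for b in range(1, N):
        out[:, b] = out[:, b - 1] + colcum[:, b]
    return out


def _brute_summary(contacts: ContactMap, electro, params: WSMEParameters,
                   T: float, field=None,
                   compute_profile: bool = True) -> EnsembleSummary:
    N = contacts.n_residues
    logws, masks = [], []
    for state in enumerate_microstates(N, None):
        g = microstate_free_energy(state, contacts, electro, params, T,
                                   field=field)
        logws.append(-g / (params.gas_constant * T))
        masks.append(state.folded_mask(N))
    logws = np.array(logws)
    masks = np.array(masks)
    log_Z = logsumexp(logws)
    pw = np.exp(logws - log_Z)
    residue_prob = pw @ masks
    m = masks.sum(axis=1)
    uH = params.contact_enthalpy(T)
    H = np.zeros(len(logws))
    for k, mask in enumerate(masks):
        h = 0.0
        for (i, j), c in contacts.pairs.items():
            if mask[i - 1:j].all():
                h += c * uH
        if electro is not None:
            for (i, j), e in electro.entries.items():
                if mask[i - 1:j].all():
                    h += 1000.0 * e
        h += float(_field_array(field, N)[mask].sum())
        H[k] = h
    mean_H = float((pw * H).sum()) / 1000.0
    profile = None
    if compute_profile:
        blog = np.array([
            logsumexp(logws[m == n]) if np.any(m == n) else NEG_INF
            for n in range(N + 1)
        ])
        profile = -params.gas_constant * T * blog / 1000.0
        profile[0] = 0.0
    return EnsembleSummary(temperature=T, log_Z=float(log_Z),
                           residue_prob=residue_prob,
                           mean_PF=float(residue_prob.mean()),
                           mean_H=mean_H, profile=profile)


def ensemble_summary(contacts: ContactMap, electro=None,
                     params: WSMEParameters | None = None,
                     T: float = 298.15, max_islands: int | None = 2,
                     field=None, compute_profile: bool = True,
                     electro_pairs: str = "all") -> EnsembleSummary:
    """Partition function, F(n) profile, per-residue probabilities and
    mean enthalpy at temperature T.

    ``max_islands``: 1 (single-stretch), 2 (double-stretch, production
    default) or None for exact 2^N enumeration (small N only).
    """
    params = params or WSMEParameters()
    if max_islands is None:
        return _brute_summary(contacts, electro, params, T, field=field,
                              compute_profile=compute_profile)
    eng = WSMEEnsemble(contacts, electro, params, field=field,
                       max_islands=max_islands, electro_pairs=electro_pairs)
    return eng.summary(T, compute_profile=compute_profile)


def heat_capacity_curve(contacts: ContactMap, electro=None,
                        params: WSMEParameters | None = None,
                        T_grid: Sequence[float] = (), max_islands: int = 2,
                        field=None) -> np.ndarray:
    """Excess heat capacity d<H>/dT (kJ/mol/K) by central differences of
    the ensemble mean enthalpy on ``T_grid`` (strictly increasing,
    step <= 1 K recommended)."""
    T_grid = np.asarray(T_grid, dtype=float)
    if len(T_grid) < 3 or np.any(np.diff(T_grid) <= 0):
        raise ValueError("T_grid must be strictly increasing with >= 3 points")
    if np.max(np.diff(T_grid)) > 1.0 + 1e-9:
        warnings.warn("temperature grid coarser than 1 K; Cp derivative may "
                      "be inaccurate")
    eng = WSMEEnsemble(contacts, electro, params, field=field,
                       max_islands=max_islands)
    H = eng.enthalpy_curve(T_grid)
    return np.gradient(H, T_grid)


def melting_temperature(T_grid: Sequence[float], pf_curve: Sequence[float]) -> float:
    """Temperature of maximum |d<P_F>/dT| (quadratic refinement around
    the grid maximum)."""
    T_grid = np.asarray(T_grid, dtype=float)
    pf = np.asarray(pf_curve, dtype=float)
    if len(T_grid) != len(pf) or len(T_grid) < 5:
        raise ValueError("need matching grids with >= 5 points")
    if np.ptp(pf) < 0.02:
        raise ValueError("no transition detected (flat P_F curve)")
    d = np.abs(np.gradient(pf, T_grid))
    i = int(np.argmax(d[1:-1])) + 1
    dm, d0, dp = d[i - 1], d[i], d[i + 1]
    denom = dm - 2 * d0 + dp
    offset = 0.0 if denom == 0 else 0.5 * (dm - dp) / denom
    offset = float(np.clip(offset, -1.0, 1.0))
    h = 0.5 * (T_grid[i + 1] - T_grid[i - 1])
    return float(T_grid[i] + offset * h)


def calibrate_xi(contacts: ContactMap, electro=None,
                 params: WSMEParameters | None = None,
                 target_tm: float = 305.0,
                 T_grid: Sequence[float] | None = None,
                 max_islands: int = 2, field=None,
                 xi_bracket: tuple[float, float] = (-3000.0, -20.0)) -> WSMEParameters:
    """Calibrate the per-contact energy xi so the model reproduces a
    target apo melting temperature (the standard way this model family is
    anchored to experiment).  Returns a copy of ``params`` with xi set."""
    params = params or WSMEParameters()
    if T_grid is None:
        T_grid = np.arange(target_tm - 65.0, target_tm + 95.0, 2.0)
    T_grid = np.asarray(T_grid, dtype=float)

    def tm_of(xi: float) -> float:
        eng = WSMEEnsemble(contacts, electro, replace(params, xi=xi),
                           field=field, max_islands=max_islands)
        pf = eng.folding_curve(T_grid)
        if np.ptp(pf) < 0.1:  # no transition inside the grid
            return T_grid[0] if pf.mean() < 0.5 else T_grid[-1]
        d = np.abs(np.gradient(pf, T_grid))
        i = int(np.argmax(d[1:-1])) + 1
        if i <= 2:  # transition at/below the lower grid edge
            return T_grid[0]
        if i >= len(T_grid) - 3:  # at/above the upper edge
            return T_grid[-1]
        return melting_temperature(T_grid, pf)

    f = lambda xi: tm_of(xi) - target_tm
    lo, hi = xi_bracket
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"target T_m {target_tm} K not bracketed by xi in {xi_bracket}: "
            f"T_m({lo}) = {flo + target_tm:.1f}, T_m({hi}) = {fhi + target_tm:.1f}"
        )
    xi_star = brentq(f, lo, hi, xtol=0.5)
    return replace(params, xi=float(xi_star))
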