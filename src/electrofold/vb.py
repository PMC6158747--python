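"""Variable-barrier (Landau) analysis of absolute DSC thermograms.

The enthalpy H (kJ/mol, relative to the characteristic temperature T0)
is the order parameter.  The free-energy functional at T0 is a piecewise
quartic with side-dependent width,

    G0(H) = -2 beta (H/a)^2 + |beta| (H/a)^4,   a = alpha1 (H < 0) or alpha2 (H >= 0)

so that beta > 0 gives a double well (minima at -alpha1 and +alpha2,
each at depth -beta, interior maximum G0(0) = 0 => barrier = beta at T0)
and beta <= 0 a single well at H = 0 (one-state / downhill).  Away from
T0 a first-order entropy closure S0(H) = H/T0 tilts the functional:

    G(H, T) = G0(H) - (T - T0) H / T0.

The asymmetry factor f = alpha1/alpha2 (low-enthalpy-side width over
high-enthalpy-side width) measures the sharpness of the native ensemble;
alpha1 + alpha2 = sigma_alpha is the energy gap.  Observables follow
from the Boltzmann density rho(H, T) ~ exp(-G(H,T)/RT); the absolute
heat capacity is a fixed folded (native) baseline plus d<H>/dT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import MEAN_RESIDUE_MASS, R_KJ


@dataclass
class VBParameters:
    """Landau-functional parameters (kJ, mol, K)."""

    sigma_alpha: float  # energy gap Sigma_alpha = alpha1 + alpha2, kJ/mol
    beta: float  # barrier height at T0 (> 0) or curvature of single well (<= 0)
    T0: float  # characteristic (apparent midpoint) temperature, K
    f: float  # asymmetry factor alpha1/alpha2

    def __post_init__(self) -> None:
        if self.sigma_alpha <= 0:
            raise ValueError("sigma_alpha must be positive")
        if self.T0 <= 0:
            raise ValueError("T0 must be positive")
        if self.f <= 0:
            raise ValueError("f must be positive")
        if self.beta > self.sigma_alpha:
            raise ValueError("beta cannot exceed sigma_alpha")

    @property
    def alpha1(self) -> float:
        return self.f * self.sigma_alpha / (1.0 + self.f)

    @property
    def alpha2(self) -> float:
        return self.sigma_alpha / (1.0 + self.f)


#: Published VB parameter sets for the CytR DNA-binding domain at the
#: three explored ionic strengths (43, 600 and 1300 mM); these are model
#: inputs used by examples, tests and the acceptance analysis.
CYTR_VB_PARAMS: dict[int, VBParameters] = {
    43: VBParameters(sigma_alpha=1554.9, beta=-173.7, T0=291.7, f=0.535),
    600: VBParameters(sigma_alpha=585.1, beta=-12.14, T0=313.6, f=0.631),
    1300: VBParameters(sigma_alpha=121.1, beta=0.12, T0=337.3, f=0.903),
}


@dataclass
class Thermogram:
    """Absolute heat capacity versus temperature."""

    temperatures: np.ndarray  # K, strictly increasing
    cp: np.ndarray  # kJ/(mol K)
    baseline_spec: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if not np.all(np.isfinite(self.cp)):
            raise ValueError("non-finite heat capacity values")

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in {**self.baseline_spec, **self.metadata}.items():
                fh.write(f"# {k}: {v}\n")
            fh.write("temperature_K,cp_kJ_mol_K\n")
            for t, c in zip(self.temperatures, self.cp):
                fh.write(f"{t:.6g},{c:.8g}\n")

    @classmethod
    def from_csv(cls, path) -> "Thermogram":
        meta: dict = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    k, _, v = line[1:].partition(":")
                    meta[k.strip()] = v.strip()
                elif line[0].isdigit() or line[0] in "+-.":
                    t, c = line.split(",")
                    rows.append((float(t), float(c)))
        arr = np.array(rows)
        cp = arr[:, 1]
        units = "".join(c for c in meta.get("units", "").lower() if c.isalnum())
        if units == "jmolk":
            cp = cp / 1000.0
        return cls(arr[:, 0], cp, metadata=meta)


@dataclass
class EnthalpyDensity:
    """Normalized probability density over the enthalpy order parameter."""

    H: np.ndarray  # kJ/mol grid
    density: np.ndarray  # 1/(kJ/mol)
    temperature: float

    def mode(self) -> float:
        return float(self.H[int(np.argmax(self.density))])

    def n_modes(self) -> int:
        d = self.density
        interior = (d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])
        return int(np.count_nonzero(interior))

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"H_kJ_mol": self.H, "density": self.density}).to_csv(
            path, index=False
        )


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def vb_g0(H, params: VBParameters):
    """Landau free-energy functional at T0, kJ/mol (vectorized over H)."""
    H = np.asarray(H, dtype=float)
    alpha = np.where(H < 0, params.alpha1, params.alpha2)
    x = H / alpha
    out = -2.0 * params.beta * x**2 + abs(params.beta) * x**4
    return out if out.ndim else float(out)


def vb_g(H, T: float, params: VBParameters):
    """Tilted functional G(H, T) = G0(H) - (T - T0) H / T0, kJ/mol."""
    H = np.asarray(H, dtype=float)
    return vb_g0(H, params) - (T - params.T0) * H / params.T0


def _h_grid(params: VBParameters, span: float = 3.0, n_points: int = 2001) -> np.ndarray:
    return np.linspace(-span * params.sigma_alpha, span * params.sigma_alpha,
                       n_points)


def vb_density(T: float, params: VBParameters, span: float = 3.0,
               n_points: int = 2001) -> EnthalpyDensity:
    """Boltzmann density over H at temperature T, trapezoid-normalized."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    H = _h_grid(params, span, n_points)
    logp = -vb_g(H, T, params) / (R_KJ * T)
    logp -= logp.max()
    p = np.exp(logp)
    norm = np.trapezoid(p, H)
    if not np.isfinite(norm) or norm <= 0:
        raise ValueError("non-normalizable density for these parameters")
    return EnthalpyDensity(H, p / norm, T)


def vb_mean_enthalpy(T_grid: Sequence[float], params: VBParameters,
                     span: float = 3.0, n_points: int = 2001) -> np.ndarray:
    """<H>(T) on a temperature grid (vectorized over T)."""
    T = np.asarray(T_grid, dtype=float)
    H = _h_grid(params, span, n_points)
    G0 = vb_g0(H, params)
    logp = (-G0[None, :] + ((T - params.T0) / params.T0)[:, None] * H[None, :]) \
        / (R_KJ * T[:, None])
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    return np.trapezoid(p * H[None, :], H, axis=1) / np.trapezoid(p, H, axis=1)


def vb_cp_curve(params: VBParameters, baseline: Callable[[np.ndarray], np.ndarray],
                T_grid: Sequence[float], span: float = 3.0,
                n_points: int = 2001, warn_coarse: bool = True) -> Thermogram:
    """Absolute heat capacity: folded baseline + d<H>/dT (central
    differences on a grid padded by one step on each side)."""
    T = np.asarray(T_grid, dtype=float)
    if len(T) < 3 or np.any(np.diff(T) <= 0):
        raise ValueError("T_grid must be strictly increasing with >= 3 points")
    step = float(np.max(np.diff(T)))
    if warn_coarse and step > 0.5 + 1e-9:
        warnings.warn("temperature grid coarser than 0.5 K; Cp derivative may "
                      "be inaccurate")
    Tpad = np.concatenate([[2 * T[0] - T[1]], T, [2 * T[-1] - T[-2]]])
    Hbar = vb_mean_enthalpy(Tpad, params, span, n_points)
    cp_excess = np.gradient(Hbar, Tpad)[1:-1]
    base = np.asarray(baseline(T), dtype=float)
    return Thermogram(T, base + cp_excess,
                      baseline_spec={"baseline": getattr(baseline, "label", "custom")},
                      metadata={"params": asdict(params)})


def barrier_height(params: VBParameters, T: float | None = None,
                   span: float = 2.0, n_points: int = 20001) -> float:
    """Free-energy barrier of G(H, T): interior maximum minus the lower
    (deeper) minimum; 0 if the functional is single-welled.  T defaults
    to T0."""
    if T is None:
        T = params.T0
    H = _h_grid(params, span, n_points)
    G = vb_g(H, T, params)
    # interior extrema by discrete curvature
    mins, maxs = [], []
    for k in range(1, len(H) - 1):
        if G[k] < G[k - 1] and G[k] <= G[k + 1]:
            mins.append(k)
        elif G[k] > G[k - 1] and G[k] >= G[k + 1]:
            maxs.append(k)
    if len(mins) < 2 or not maxs:
        return 0.0
    k_lo = min(mins, key=lambda k: G[k])
    interior = [k for k in maxs if min(mins) < k < max(mins)]
    if not interior:
        return 0.0
    k_max = max(interior, key=lambda k: G[k])
    return float(_parabolic_value(H, G, k_max, sign=+1)
                 - _parabolic_value(H, G, k_lo, sign=-1))


def _parabolic_value(x: np.ndarray, y: np.ndarray, k: int, sign: int) -> float:
    """Refined extremum value via a parabola through (k-1, k, k+1)."""
    if k <= 0 or k >= len(x) - 1:
        return float(y[k])
    ym, y0, yp = y[k - 1], y[k], y[k + 1]
    denom = ym - 2 * y0 + yp
    if denom == 0:
        return float(y0)
    return float(y0 - (ym - yp) ** 2 / (8 * denom))


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

def freire_baseline(chain_spec: int | float, by_mass: bool = False
                    ) -> Callable[[np.ndarray], np.ndarray]:
    """Fixed folded-state (native) absolute heat capacity baseline.

    Linear-in-T parameterization of the native-state heat capacity per
    gram of protein, cp(T) = 1.323 + 6.70e-3 (T - 293.15) J g^-1 K^-1
    (per-gram native baseline of the absolute-Cp literature), converted
    to kJ mol^-1 K^-1 with a mean residue mass of 110 g/mol when
    ``chain_spec`` is a residue count.
    """
    molar_mass = float(chain_spec) if by_mass else float(chain_spec) * MEAN_RESIDUE_MASS

    def baseline(T):
        T = np.asarray(T, dtype=float)
        cp_per_g = 1.323 + 6.70e-3 * (T - 293.15)  # J / (g K)
        out = molar_mass * cp_per_g / 1000.0
        return out if out.ndim else float(out)

    baseline.label = f"freire_folded(M={molar_mass:g})"
    baseline.molar_mass = molar_mass
    return baseline


def makhatadze_privalov_baseline(chain_spec: int | float, by_mass: bool = False
                                 ) -> Callable[[np.ndarray], np.ndarray]:
    """Unfolded-state absolute heat capacity baseline (plotting aid only;
    never used in fitting).  Approximate quadratic per-gram form of the
    unfolded-chain calorimetric literature."""
    molar_mass = float(chain_spec) if by_mass else float(chain_spec) * MEAN_RESIDUE_MASS

    def baseline(T):
        T = np.asarray(T, dtype=float)
        t = T - 273.15
        cp_per_g = 1.75 + 6.2e-3 * t - 3.0e-5 * t**2  # J / (g K)
        out = molar_mass * cp_per_g / 1000.0
        return out if out.ndim else float(out)

    baseline.label = f"makhatadze_privalov_unfolded(M={molar_mass:g})"
    return baseline


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class VBFitResult:
    params: VBParameters
    residual_rms: float  # kJ/(mol K)
    diagnostics: dict


def fit_thermogram(data: Thermogram,
                   baseline: Callable[[np.ndarray], np.ndarray],
                   init: VBParameters | None = None, seed: int = 0,
                   n_starts: int = 8, n_points: int = 2001) -> VBFitResult:
    """Bounded nonlinear least squares for (sigma_alpha, beta, T0, f)
    with the folded baseline held fixed.

    Deterministic multi-start: starts span both signs of beta and a
    range of energy gaps around data-driven heuristics; ``seed`` drives
    small reproducible jitter of the start points.
    """
    T = data.temperatures
    y = data.cp
    excess = y - np.asarray(baseline(T), dtype=float)
    T0_guess = float(T[int(np.argmax(excess))])
    scale = max(float(np.trapezoid(np.clip(excess, 0, None), T)), 10.0)

    lb = np.array([10.0, -500.0, T[0] - 30.0, 0.05])
    ub = np.array([8000.0, 300.0, T[-1] + 30.0, 20.0])

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    if init is not None:
        starts.append(np.array([init.sigma_alpha, init.beta, init.T0, init.f]))
    betas = [-150.0, -10.0, 0.1, 1.0]
    gaps = [scale, 4.0 * scale]
    for b in betas:
        for g in gaps:
            jitter = 1.0 + 0.02 * rng.standard_normal()
            starts.append(np.array([g * jitter, b, T0_guess, 0.8]))
    starts = starts[:max(n_starts, 1) + (init is not None)]

    def residual(theta: np.ndarray) -> np.ndarray:
        p = VBParameters(sigma_alpha=theta[0],
                         beta=min(theta[1], theta[0]),
                         T0=theta[2], f=theta[3])
        model = vb_cp_curve(p, baseline, T, n_points=n_points,
                            warn_coarse=False)
        return model.cp - y

    best = None
    trace = []
    for s in starts:
        s = np.clip(s, lb + 1e-9, ub - 1e-9)
        try:
            res = least_squares(residual, s, bounds=(lb, ub), method="trf",
                                xtol=1e-10, ftol=1e-12, max_nfev=400)
        except Exception as exc:  # pathological start
            trace.append({"start": s.tolist(), "error": str(exc)})
            continue
        trace.append({"start": s.tolist(), "cost": float(res.cost),
                      "x": res.x.tolist(), "success": bool(res.success)})
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(f"VB fit failed from all starts: {trace}")
    theta = best.x
    params = VBParameters(sigma_alpha=float(theta[0]), beta=float(theta[1]),
                          T0=float(theta[2]), f=float(theta[3]))
    rms = float(np.sqrt(np.mean(residual(theta) ** 2)))
    return VBFitResult(params=params, residual_rms=rms,
                       diagnostics={"seed": seed, "n_starts": len(starts),
                                    "cost": float(best.cost), "trace": trace})
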