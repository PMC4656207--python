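"""sigma-A estimation, figures of merit, and weighted phase combination.

sigma-A is the per-resolution-shell correlation between normalized observed
and model amplitudes (E-values); it drives both the figure of merit of a
phase set (the expected cosine of its phase error) and the weights used when
two independent phase sources are combined.

The combination algebra is unimodal von Mises: each phase source with
figure of merit m is treated as a von Mises distribution whose concentration
X satisfies m = I1(X)/I0(X); concentrations add vectorially.  Both phase
sources in this package (density-modified phases and auto-built-model
phases) are unimodal, so the full Hendrickson-Lattman machinery is not
needed.
"""

from __future__ import annotations

import numpy as np
from scipy.special import i0e, i1e

from .core import ReflectionSet
from .emprep import ShellCurve

__all__ = [
    "resolution_shells",
    "normalize_amplitudes",
    "estimate_sigma_a",
    "fom_from_X",
    "fom_from_sigma_a",
    "fom_to_concentration",
    "combine_phases",
]

SIGMA_A_MAX = 0.999
FOM_MAX = 0.9999
MIN_PER_SHELL = 8


def resolution_shells(d: np.ndarray, n_shells: int, min_per_shell: int = MIN_PER_SHELL
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Equal-count resolution shells.

    Returns (shell_index per reflection, shell d-boundaries d_max->d_min of
    length n_kept+1).  Shells that would hold fewer than ``min_per_shell``
    reflections are merged with their neighbour.
    """
    d = np.asarray(d, float)
    n = len(d)
    n_shells = max(1, min(n_shells, n // max(min_per_shell, 1) or 1))
    order = np.argsort(-d)  # low resolution (large d) first
    bounds = np.linspace(0, n, n_shells + 1).astype(int)
    idx = np.empty(n, int)
    for s in range(n_shells):
        idx[order[bounds[s]:bounds[s + 1]]] = s
    edges = np.empty(n_shells + 1)
    edges[0] = d.max() + 1e-9
    for s in range(1, n_shells):
        edges[s] = d[order[bounds[s]]]
    edges[-1] = d.min() - 1e-9
    return idx, edges


def normalize_amplitudes(refl: ReflectionSet, n_shells: int = 20) -> ReflectionSet:
    """E-values: amplitudes scaled so each resolution shell has <E^2> = 1."""
    idx, _ = resolution_shells(refl.d, n_shells)
    E = refl.F.astype(float).copy()
    for s in range(idx.max() + 1):
        sel = idx == s
        ms = np.mean(refl.F[sel] ** 2)
        E[sel] = refl.F[sel] / np.sqrt(ms) if ms > 0 else 0.0
    return refl.copy(F=E)


def estimate_sigma_a(
    e_obs: ReflectionSet,
    e_calc: ReflectionSet,
    n_shells: int = 20,
) -> ShellCurve:
    """Shellwise sigma-A as the correlation of normalized amplitudes.

    Per shell, sigmaA = Pearson correlation of matched (E_obs, E_calc),
    clipped to [0, 0.999].  A centered moment estimator is required because
    E-values are positive: the raw product <E_obs*E_calc> is ~0.8 even for
    independent sets, whereas the correlation has the right limits (1 for a
    perfect model, 0 +/- 1/sqrt(n) under the null).  This transparent
    estimator replaces the maximum-likelihood refinement of full SIGMAA;
    same limits, simpler to test.  Shells with fewer than 8 matched
    reflections are merged with a neighbour.
    """
    ia, ib = e_obs.match(e_calc)
    if len(ia) == 0:
        raise ValueError("no common reflections between observed and calculated sets")
    d = e_obs.d[ia]
    a = e_obs.F[ia]
    b = e_calc.F[ib]
    idx, edges = resolution_shells(d, n_shells)
    n_kept = idx.max() + 1
    vals = np.empty(n_kept)
    for s in range(n_kept):
        sel = idx == s
        da = a[sel] - a[sel].mean()
        db = b[sel] - b[sel].mean()
        den = np.sqrt((da * da).sum() * (db * db).sum())
        vals[s] = np.clip((da * db).sum() / den if den > 0 else 0.0,
                          0.0, SIGMA_A_MAX)
    return ShellCurve(d_max=edges[:-1], d_min=edges[1:], value=vals)


def fom_from_X(X: np.ndarray) -> np.ndarray:
    """Figure of merit m = I1(X)/I0(X) (acentric Sim weight)."""
    X = np.asarray(X, float)
    return i1e(X) / i0e(X)


def fom_from_sigma_a(
    sigA: ShellCurve,
    e_obs: np.ndarray,
    e_calc: np.ndarray,
    d: np.ndarray,
    centric: np.ndarray | None = None,
) -> np.ndarray:
    """Per-reflection figure of merit from shellwise sigma-A.

    X = 2*sigmaA*E_obs*E_calc / (1 - sigmaA^2); acentric reflections use
    m = I1(X)/I0(X), centric ones m = tanh(X/2).
    """
    sa = sigA.lookup(np.asarray(d, float))
    X = 2.0 * sa * np.asarray(e_obs) * np.asarray(e_calc) / (1.0 - sa**2)
    m = fom_from_X(X)
    if centric is not None and np.any(centric):
        m = np.where(centric, np.tanh(X / 2.0), m)
    return np.clip(m, 0.0, FOM_MAX)


def fom_to_concentration(m: float | np.ndarray, tol: float = 1e-10) -> float | np.ndarray:
    """Numeric inverse of m = I1(X)/I0(X) (von Mises concentration).

    Vectorized: the Best-Fisher piecewise approximation seeds a Newton
    iteration on f(X) = I1(X)/I0(X) - m, whose derivative is
    1 - A^2 - A/X with A = I1/I0.  m is clipped to [0, 0.9999] first —
    the concentration diverges as m -> 1.
    """
    scalar = np.isscalar(m)
    mm = np.clip(np.atleast_1d(np.asarray(m, float)), 0.0, FOM_MAX)
    X = np.where(
        mm < 0.53,
        2.0 * mm + mm**3 + 5.0 * mm**5 / 6.0,
        np.where(mm < 0.85, -0.4 + 1.39 * mm + 0.43 / (1.0 - mm),
                 1.0 / np.maximum(mm**3 - 4.0 * mm**2 + 3.0 * mm, 1e-12)),
    )
    zero = mm <= 0.0
    X = np.where(zero, 0.0, np.maximum(X, 1e-12))
    for _ in range(60):
        A = fom_from_X(X)
        with np.errstate(divide="ignore", invalid="ignore"):
            deriv = np.where(X > 1e-8, 1.0 - A * A - A / np.maximum(X, 1e-300), 0.5)
        step = np.where(zero, 0.0, (A - mm) / np.maximum(deriv, 1e-12))
        X = np.maximum(X - step, 0.0)
        if np.all(np.abs(step) < tol):
            break
    return float(X[0]) if scalar else X


def combine_phases(src1: ReflectionSet, src2: ReflectionSet) -> ReflectionSet:
    """Unimodal von Mises combination of two phase sources.

    Each source contributes a vector of length X_i = concentration(m_i) along
    its phase; the combined phase is the resultant direction and the combined
    figure of merit is I1(|resultant|)/I0(|resultant|).  Reflections present
    in only one source pass through unchanged.  Exact cancellation
    (antiparallel, equal weight) yields fom 0 and an arbitrary phase.
    """
    for name, src in (("first", src1), ("second", src2)):
        if src.phi is None or src.fom is None:
            raise ValueError(f"{name} source needs both phases and figures of merit")
    ia, ib = src1.match(src2)
    out = src1.copy()
    X1 = np.asarray(fom_to_concentration(src1.fom[ia]))
    X2 = np.asarray(fom_to_concentration(src2.fom[ib]))
    p1 = np.radians(src1.phi[ia])
    p2 = np.radians(src2.phi[ib])
    A = X1 * np.cos(p1) + X2 * np.cos(p2)
    B = X1 * np.sin(p1) + X2 * np.sin(p2)
    R = np.hypot(A, B)
    out.phi[ia] = np.degrees(np.arctan2(B, A)) % 360.0
    out.fom[ia] = np.clip(fom_from_X(R), 0.0, FOM_MAX)

    # append reflections only present in src2
    only2 = np.setdiff1d(np.arange(len(src2)), ib)
    if len(only2):
        extra = src2.select(only2)
        out = ReflectionSet(
            cell=out.cell,
            hkl=np.vstack([out.hkl, extra.hkl]),
            F=np.concatenate([out.F, extra.F]),
            phi=np.concatenate([out.phi, extra.phi]),
            fom=np.concatenate([out.fom, extra.fom]),
        )
    return out
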