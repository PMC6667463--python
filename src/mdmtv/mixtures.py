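"""Linear mixing of relaxivity signatures and composition unmixing.

Forward model: the MTV dependency of a mixture is the fraction-weighted
linear sum of the dependencies of its pure components — for each qMRI
parameter, slope_mix = sum_i f_i * slope_i (and likewise intercepts).  This
is the fast-exchange additivity of relaxation contributions.

Inverse model: given an observed signature m (the slope vector across qMRI
parameters) and a library whose columns are pure-component slope vectors,
estimate the fractions f by least squares on A f = m, optionally
constrained to the probability simplex.  The unconstrained path is the
classic QR-factorization least-squares solve.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CollinearLibraryError, DataError
from .relaxivity import LinearDependency, MDMSignature

__all__ = [
    "ComponentLibrary",
    "MixtureDesign",
    "predict_mixture_dependency",
    "predict_mixture_qmri",
    "unmix",
]

_RANK_RCOND = 1e-10


@dataclass
class ComponentLibrary:
    """Pure-component MTV dependencies, one signature per component.

    ``components`` maps a component name (e.g. a lipid) to
    ``{param: (slope, intercept)}``.  All components must cover the same
    parameter set.
    """

    components: dict  # name -> {param: (slope, intercept)}

    def __post_init__(self):
        if not self.components:
            raise DataError("library needs at least one component")
        param_sets = {name: tuple(sorted(c)) for name, c in self.components.items()}
        if len(set(param_sets.values())) > 1:
            raise DataError(f"components cover different parameter sets: {param_sets}")

    @property
    def names(self) -> tuple:
        return tuple(self.components)

    @property
    def params(self) -> tuple:
        return tuple(sorted(next(iter(self.components.values()))))

    def slope_matrix(self, params=None) -> np.ndarray:
        """Matrix A with one column of slopes per component (params x comps)."""
        params = self.params if params is None else tuple(params)
        return np.array(
            [[self.components[c][p][0] for c in self.names] for p in params]
        )

    def intercept_matrix(self, params=None) -> np.ndarray:
        params = self.params if params is None else tuple(params)
        return np.array(
            [[self.components[c][p][1] for c in self.names] for p in params]
        )

    @classmethod
    def from_signatures(cls, signatures: dict) -> "ComponentLibrary":
        """Build from ``{name: MDMSignature}`` (phantom fits of pure samples)."""
        comps = {
            name: {p: (d.slope, d.intercept) for p, d in sig.fits.items()}
            for name, sig in signatures.items()
        }
        return cls(comps)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ComponentLibrary":
        """Read a tidy CSV with columns component,param,slope,intercept."""
        df = pd.read_csv(path)
        comps: dict = {}
        for row in df.itertuples():
            comps.setdefault(row.component, {})[row.param] = (
                float(row.slope),
                float(getattr(row, "intercept", 0.0)),
            )
        return cls(comps)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            dict(component=c, param=p, slope=sl, intercept=ic)
            for c in self.names
            for p, (sl, ic) in sorted(self.components[c].items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class MixtureDesign:
    """Component fractions of one mixture.

    Fractions are nonnegative; with ``sum_to_one`` they must total 1 within
    1e-9 (a composition), otherwise they are free nonnegative weights.
    """

    fractions: dict  # component name -> fraction
    sum_to_one: bool = True

    def __post_init__(self):
        for name, f in self.fractions.items():
            if f < 0:
                raise DataError(f"negative fraction {f} for {name!r}")
        if self.sum_to_one:
            total = sum(self.fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise DataError(f"fractions sum to {total}, expected 1")

    def vector(self, names) -> np.ndarray:
        return np.array([self.fractions.get(n, 0.0) for n in names])


def predict_mixture_dependency(
    library: ComponentLibrary, design: MixtureDesign
) -> MDMSignature:
    """Fraction-weighted linear sum of pure-component dependencies."""
    unknown = set(design.fractions) - set(library.names)
    if unknown:
        raise DataError(f"design components not in library: {sorted(unknown)}")
    f = design.vector(library.names)
    slopes = library.slope_matrix() @ f
    intercepts = library.intercept_matrix() @ f
    sig = MDMSignature(region="mixture", subject="predicted")
    for p, a, b in zip(library.params, slopes, intercepts):
        sig.fits[p] = LinearDependency(param=p, slope=float(a), intercept=float(b))
    return sig


def predict_mixture_qmri(
    library: ComponentLibrary, design: MixtureDesign, mtv: float
) -> dict:
    """Evaluate the mixed linear laws at a total MTV value."""
    if not 0 <= mtv < 1:
        raise DataError(f"MTV {mtv} outside [0, 1)")
    sig = predict_mixture_dependency(library, design)
    return {p: float(d.predict(mtv)) for p, d in sig.fits.items()}


def _constrained_ls(A: np.ndarray, m: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Solve min ||A_S f - m|| s.t. sum(f) = 1 on the given support via KKT."""
    As = A[:, support]
    k = As.shape[1]
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = As.T @ As
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.concatenate([As.T @ m, [1.0]])
    sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
    return sol[:k]


def unmix(
    observed,
    library: ComponentLibrary,
    constraints: str = "NONNEG_SUM_TO_ONE",
    use_intercepts: bool = False,
) -> tuple[MixtureDesign, float, dict]:
    """Estimate component fractions from an observed MDM signature.

    Parameters
    ----------
    observed
        An :class:`~mdmtv.relaxivity.MDMSignature` or ``{param: slope}``
        mapping; must cover the library's parameters.
    constraints
        'NONE' — plain least squares (QR); 'SUM_TO_ONE' — equality
        constrained; 'NONNEG_SUM_TO_ONE' — simplex constrained (default:
        compositions are fractions).
    use_intercepts
        Also match intercepts (stacks intercept rows under the slope rows).

    Returns
    -------
    (design, residual_norm, diagnostics)
        Diagnostics carry the condition number, rank and an
        ``underdetermined`` flag.

    Raises
    ------
    CollinearLibraryError
        If the component matrix is rank-deficient (collinear signatures).
    """
    params = library.params
    if isinstance(observed, MDMSignature):
        missing = set(params) - set(observed.fits)
        if missing:
            raise DataError(f"observed signature lacks parameters: {sorted(missing)}")
        m = observed.slopes(params)
        m_int = observed.intercepts(params)
    else:
        missing = set(params) - set(observed)
        if missing:
            raise DataError(f"observed values lack parameters: {sorted(missing)}")
        m = np.array([float(observed[p]) for p in params])
        m_int = None
    A = library.slope_matrix(params)
    if use_intercepts:
        if m_int is None:
            raise DataError("use_intercepts requires an MDMSignature with intercepts")
        A = np.vstack([A, library.intercept_matrix(params)])
        m = np.concatenate([m, m_int])
    n_obs, n_comp = A.shape
    rank = np.linalg.matrix_rank(A, tol=None)
    cond = float(np.linalg.cond(A))
    if rank < n_comp:
        raise CollinearLibraryError(
            f"component matrix rank {rank} < {n_comp} components "
            f"(condition number {cond:.3g})",
            condition_number=cond,
        )
    underdetermined = n_obs < n_comp
    if underdetermined:
        warnings.warn(
            f"underdetermined system ({n_obs} observations, {n_comp} components): "
            "returning the minimum-norm solution",
            stacklevel=2,
        )
    if constraints == "NONE":
        f = np.linalg.lstsq(A, m, rcond=None)[0]
        sum_flag = False
    elif constraints == "SUM_TO_ONE":
        f = _constrained_ls(A, m, np.arange(n_comp))
        sum_flag = True
    elif constraints == "NONNEG_SUM_TO_ONE":
        f = _simplex_ls(A, m)
        sum_flag = True
    else:
        raise ValueError(f"unknown constraints {constraints!r}")
    residual = float(np.linalg.norm(A @ f - m))
    fractions = {name: float(v) for name, v in zip(library.names, f)}
    design = MixtureDesign(fractions=fractions, sum_to_one=False)
    design.sum_to_one = sum_flag  # validated below only for simplex output
    if constraints == "NONNEG_SUM_TO_ONE":
        # renormalise away the KKT solver's floating-point slack
        total = sum(fractions.values())
        design = MixtureDesign(
            fractions={k: v / total for k, v in fractions.items()}, sum_to_one=True
        )
    diagnostics = {
        "condition_number": cond,
        "rank": int(rank),
        "underdetermined": underdetermined,
        "constraints": constraints,
    }
    return design, residual, diagnostics


def _simplex_ls(A: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Exact simplex-constrained least squares by support enumeration.

    For small component counts (<= 12) every nonempty support set is tried:
    the equality-constrained problem is solved on the support and feasible
    candidates (all fractions >= 0) compete on residual norm.  Exact, and
    the output lies exactly on the simplex.
    """
    n_comp = A.shape[1]
    if n_comp > 12:
        return _simplex_ls_iterative(A, m)
    best, best_res = None, np.inf
    for size in range(1, n_comp + 1):
        for support in itertools.combinations(range(n_comp), size):
            idx = np.array(support)
            f_s = _constrained_ls(A, m, idx)
            if np.any(f_s < -1e-12):
                continue
            f = np.zeros(n_comp)
            f[idx] = np.clip(f_s, 0.0, None)
            res = float(np.linalg.norm(A @ f - m))
            if res < best_res - 1e-15:
                best, best_res = f, res
    assert best is not None  # size-1 supports are always feasible
    return best


def _simplex_ls_iterative(A: np.ndarray, m: np.ndarray) -> np.ndarray:
    """SLSQP fallback for large component counts."""
    from scipy.optimize import minimize

    n_comp = A.shape[1]
    x0 = np.full(n_comp, 1.0 / n_comp)
    res = minimize(
        lambda f: float(np.sum((A @ f - m) ** 2)),
        x0,
        jac=lambda f: 2.0 * A.T @ (A @ f - m),
        bounds=[(0.0, 1.0)] * n_comp,
        constraints=[{"type": "eq", "fun": lambda f: np.sum(f) - 1.0}],
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 500},
    )
    f = np.clip(res.x, 0.0, None)
    return f / f.sum()
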