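"""Closed-form Gaussian information measures for network inference.

Under a multivariate-Gaussian model of expression profiles every quantity
used by the inference engine — mutual information (MI), conditional mutual
information (CMI), the KL-divergence causal strength of a single directed
edge, and the conditional mutual *inclusive* information (CMI2) — reduces to
covariance algebra.  CMI2 for a pair (X, Y) given a conditioning set Z is
defined as the average of the two KL divergences between the joint
distribution and the two "edge-severed" interventional distributions

    CMI2(X;Y|Z) = ( D_KL(P || P_{X->Y}) + D_KL(P || P_{Y->X}) ) / 2,

where P_{X->Y} replaces Y's conditional law given (Z, X) by its average
over the marginal of X, i.e. it deletes the direct X->Y dependence while
keeping the (X, Z) marginal intact.  CMI2 dominates CMI (the gap is a sum
of two nonnegative KL terms) and therefore does not collapse to zero when
the conditioning variable is nearly collinear with X or Y — the failure
mode that makes plain CMI underestimate direct regulation.

Two independent routes to CMI2 are provided: :func:`cmi2` evaluates a
closed-form trace/log-determinant expression built from the severed
covariances, and :func:`cmi2_oracle` composes :func:`interventional_model`
with :func:`kl_gaussian`.  The oracle is the normative definition; the
closed form is required (and tested) to match it to high precision.

All logarithms are natural, so every measure is in nats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateModelError, InputError, InternalConsistencyError

__all__ = [
    "GaussianModel",
    "TripleQuery",
    "fit_gaussian",
    "mi",
    "cmi",
    "interventional_model",
    "kl_gaussian",
    "causal_strength",
    "cmi2",
    "cmi2_oracle",
    "partial_correlation",
]

#: determinant below this is treated as exactly singular
DET_FLOOR = 1e-300
#: covariance condition number above this triggers the degeneracy policy
COND_LIMIT = 1e12
#: analytic nonnegatives may undershoot zero by at most this much
NEG_TOL = 1e-12

_SYM_TOL = 1e-10


@dataclass(frozen=True)
class GaussianModel:
    """A multivariate Gaussian over a named, ordered variable set.

    Parameters
    ----------
    variables
        Unique variable (gene) names, fixing the coordinate order of
        ``mean`` and ``covariance``.
    mean
        Mean vector, one entry per variable.
    covariance
        Symmetric positive-semidefinite covariance matrix.
    preprocessing
        Free-form provenance of how the model was fitted (log transform,
        standardization, sample count); informational only.
    """

    variables: tuple[str, ...]
    mean: np.ndarray
    covariance: np.ndarray
    preprocessing: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "covariance", np.asarray(self.covariance, dtype=float))
        p = len(self.variables)
        if len(set(self.variables)) != p:
            raise InputError("variable names must be unique")
        if self.mean.shape != (p,):
            raise InputError(f"mean has shape {self.mean.shape}, expected ({p},)")
        if self.covariance.shape != (p, p):
            raise InputError(
                f"covariance has shape {self.covariance.shape}, expected ({p}, {p})"
            )
        asym = np.max(np.abs(self.covariance - self.covariance.T), initial=0.0)
        if asym > _SYM_TOL:
            raise InputError(f"covariance asymmetric by {asym:.3g} (> {_SYM_TOL:g})")
        eig = np.linalg.eigvalsh(self.covariance)
        if p and eig[0] < -1e-10 * max(eig[-1], 1.0):
            raise InputError(f"covariance not positive semi-definite (min eig {eig[0]:.3g})")

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def rank_deficient(self) -> bool:
        """True when the covariance is numerically rank-deficient (e.g. two
        variables with identical profiles)."""
        eig = np.linalg.eigvalsh(self.covariance)
        return bool(eig[0] <= 1e-12 * max(eig[-1], 1.0))

    def index(self, name: str) -> int:
        try:
            return self.variables.index(name)
        except ValueError:
            raise InputError(f"unknown variable {name!r}") from None

    def submodel(self, names: list[str] | tuple[str, ...]) -> "GaussianModel":
        """Marginal model over ``names`` in the given order."""
        idx = [self.index(n) for n in names]
        return GaussianModel(
            tuple(names),
            self.mean[idx],
            self.covariance[np.ix_(idx, idx)],
            preprocessing=self.preprocessing,
        )


@dataclass(frozen=True)
class TripleQuery:
    """A conditional query: pair (x, y) given conditioning set z.

    ``len(z)`` is the order of the query; order 0 (empty z) corresponds to
    plain mutual information.
    """

    x: str
    y: str
    z: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "z", tuple(self.z))
        if self.x == self.y:
            raise InputError("x and y must differ")
        if self.x in self.z or self.y in self.z:
            raise InputError("x and y may not appear in the conditioning set")
        if len(set(self.z)) != len(self.z):
            raise InputError("conditioning set contains duplicates")

    @property
    def order(self) -> int:
        return len(self.z)

    def validate(self, model: GaussianModel) -> None:
        for n in (self.x, self.y, *self.z):
            model.index(n)


# ---------------------------------------------------------------------------
# fitting


def fit_gaussian(
    expr,
    *,
    log_transform: bool = False,
    pseudocount: float = 0.0,
    standardize: bool = False,
) -> GaussianModel:
    """Fit a Gaussian model (sample mean, sample covariance with m-1
    denominator) to an expression matrix.

    ``expr`` may be an :class:`~cmi2ni.io.ExpressionMatrix` or a pandas
    DataFrame with genes as rows and samples as columns.  ``log_transform``
    applies ``ln(value + pseudocount)`` per cell — expression intensities
    are commonly log-transformed to better match the Gaussian assumption —
    and requires every shifted value to be positive.  ``standardize``
    scales each gene to zero mean and unit variance (informationally
    neutral for MI/CMI/CMI2, which are scale invariant).
    """
    genes, samples, values = _as_matrix(expr)
    if values.shape[1] < 2:
        raise InputError("at least 2 samples are required to fit a covariance")
    if not np.all(np.isfinite(values)):
        g, s = np.argwhere(~np.isfinite(values))[0]
        raise InputError(
            f"non-finite expression value for gene {genes[g]!r}, sample {samples[s]!r}"
        )
    if log_transform:
        shifted = values + pseudocount
        if np.any(shifted <= 0):
            g, s = np.argwhere(shifted <= 0)[0]
            raise InputError(
                f"log-transform requires positive values; gene {genes[g]!r}, "
                f"sample {samples[s]!r} is {values[g, s]!r} "
                f"(pseudocount {pseudocount})"
            )
        values = np.log(shifted)
    if standardize:
        sd = values.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            g = int(np.argwhere(sd.ravel() == 0)[0][0])
            raise InputError(f"gene {genes[g]!r} has zero variance; cannot standardize")
        values = (values - values.mean(axis=1, keepdims=True)) / sd
    mean = values.mean(axis=1)
    cov = np.cov(values, ddof=1)
    cov = np.atleast_2d(cov)
    # guard against tiny asymmetry from accumulated rounding
    cov = 0.5 * (cov + cov.T)
    return GaussianModel(
        tuple(genes),
        mean,
        cov,
        preprocessing={
            "log_transform": log_transform,
            "pseudocount": pseudocount,
            "standardize": standardize,
            "n_samples": int(values.shape[1]),
        },
    )


def _as_matrix(expr):
    if hasattr(expr, "genes") and hasattr(expr, "values"):
        return list(expr.genes), list(expr.samples), np.asarray(expr.values, float)
    import pandas as pd

    if isinstance(expr, pd.DataFrame):
        return (
            [str(g) for g in expr.index],
            [str(s) for s in expr.columns],
            expr.to_numpy(dtype=float),
        )
    raise InputError(f"cannot interpret {type(expr).__name__} as an expression matrix")


# ---------------------------------------------------------------------------
# numerical policy helpers


def _prepare_cov(cov: np.ndarray, strict: bool) -> np.ndarray:
    """Apply the degeneracy policy to a covariance submatrix.

    Near-singular covariances are expected inputs (near-duplicate
    expression profiles).  In lenient mode (default) they receive a ridge
    ``lambda*I`` with ``lambda = 1e-10 * trace/dim``; in strict mode they
    raise :class:`DegenerateModelError`.
    """
    cov = np.asarray(cov, float)
    if cov.size == 0:
        return cov
    eig = np.linalg.eigvalsh(cov)
    cond = np.inf if eig[0] <= 0 else eig[-1] / eig[0]
    sign, logdet = np.linalg.slogdet(cov)
    degenerate = sign <= 0 or logdet < np.log(DET_FLOOR) or cond > COND_LIMIT
    if not degenerate:
        return cov
    if strict:
        raise DegenerateModelError(
            f"covariance is numerically degenerate (condition {cond:.3g})"
        )
    lam = 1e-10 * np.trace(cov) / cov.shape[0]
    if lam <= 0:
        raise DegenerateModelError("covariance has nonpositive trace; cannot regularize")
    return cov + lam * np.eye(cov.shape[0])


def _logdet(cov: np.ndarray) -> float:
    if cov.size == 0:
        return 0.0
    sign, val = np.linalg.slogdet(cov)
    if sign <= 0 or val < np.log(DET_FLOOR):
        raise DegenerateModelError("determinant underflow in log-det computation")
    return float(val)


def _clamp_nonneg(value: float, what: str) -> float:
    if value >= 0:
        return float(value)
    if value >= -NEG_TOL:
        return 0.0
    raise InternalConsistencyError(f"{what} evaluated to {value!r} < -{NEG_TOL:g}")


# ---------------------------------------------------------------------------
# MI / CMI


def mi(model: GaussianModel, x: str, y: str, *, strict: bool = False) -> float:
    """Gaussian mutual information MI(X;Y) = ½ ln(|C_X||C_Y| / |C_XY|), nats."""
    if x == y:
        raise InputError("x and y must differ")
    cov = _prepare_cov(model.submodel([x, y]).covariance, strict)
    val = 0.5 * (np.log(cov[0, 0]) + np.log(cov[1, 1]) - _logdet(cov))
    return _clamp_nonneg(val, "mutual information")


def cmi(model: GaussianModel, q: TripleQuery, *, strict: bool = False) -> float:
    """Gaussian conditional mutual information
    CMI(X;Y|Z) = ½ ln(|C_XZ||C_YZ| / (|C_Z||C_XYZ|)), nats.

    Supports conditioning sets of any order ≥ 1; for empty z use :func:`mi`.
    """
    q.validate(model)
    if q.order == 0:
        raise InputError("cmi requires a non-empty conditioning set; use mi for order 0")
    names = [q.x, q.y, *q.z]
    cov = _prepare_cov(model.submodel(names).covariance, strict)
    zi = list(range(2, 2 + q.order))
    ld = lambda ii: _logdet(cov[np.ix_(ii, ii)])
    val = 0.5 * (ld([0, *zi]) + ld([1, *zi]) - ld(zi) - ld([0, 1, *zi]))
    return _clamp_nonneg(val, "conditional mutual information")


# ---------------------------------------------------------------------------
# interventional Gaussians and KL divergence


def interventional_model(
    model: GaussianModel, q: TripleQuery, direction: str, *, strict: bool = False
) -> GaussianModel:
    """The edge-severed ("interventional") Gaussian over (x, y, z).

    For direction ``"x->y"`` the joint P(x, y, z) is replaced by
    P(x, z) · ∫ P(y | z, x') P(x') dx': the (x, z) marginal is kept exactly
    and y's conditional law given z is the original conditional averaged
    over an independent copy of x.  Concretely, writing the original
    conditional as  y | x, z ~ N(mu_y + b_x (x - mu_x) + b_z'(z - mu_z), s),
    the severed model sets  y = mu_y + b_z'(z - mu_z) + e  with
    e ~ N(0, s + b_x^2 Var(x)) independent of (x, z).  The result is again
    Gaussian, with unchanged mean.
    """
    q.validate(model)
    if direction not in ("x->y", "y->x"):
        raise InputError(f"direction must be 'x->y' or 'y->x', got {direction!r}")
    names = [q.x, q.y, *q.z]
    sub = model.submodel(names)
    cov = _prepare_cov(sub.covariance, strict)
    child, parent = (1, 0) if direction == "x->y" else (0, 1)
    new_cov = _sever_child(cov, child=child, parent=parent, z_idx=list(range(2, cov.shape[0])))
    return GaussianModel(sub.variables, sub.mean, new_cov, preprocessing=sub.preprocessing)


def _sever_child(cov: np.ndarray, child: int, parent: int, z_idx: list[int]) -> np.ndarray:
    """Covariance of the severed joint: regression-view construction."""
    pz = [parent, *z_idx]
    b = np.linalg.solve(cov[np.ix_(pz, pz)], cov[np.ix_(pz, [child])]).ravel()
    resid = cov[child, child] - cov[child, pz] @ b
    b_p, b_z = b[0], b[1:]
    out = cov.copy()
    for v in range(cov.shape[0]):
        if v == child:
            continue
        out[child, v] = out[v, child] = b_z @ cov[np.ix_(z_idx, [v])].ravel() if z_idx else 0.0
    var_child = (b_z @ cov[np.ix_(z_idx, z_idx)] @ b_z if z_idx else 0.0)
    out[child, child] = var_child + max(resid, 0.0) + b_p**2 * cov[parent, parent]
    return 0.5 * (out + out.T)


def kl_gaussian(p: GaussianModel, q: GaussianModel) -> float:
    """KL divergence D_KL(p || q) between Gaussians on the same variables.

    Standard closed form
    ½ [ tr(Σq⁻¹Σp) + (μq−μp)ᵀ Σq⁻¹ (μq−μp) − n + ln(|Σq|/|Σp|) ].
    """
    if p.variables != q.variables:
        raise InputError(
            f"variable mismatch: {p.variables} vs {q.variables} (same names, same order required)"
        )
    n = p.n_variables
    sq = np.asarray(q.covariance)
    sp = np.asarray(p.covariance)
    sign, logdet_q = np.linalg.slogdet(sq)
    if sign <= 0:
        raise DegenerateModelError("q covariance is singular; KL undefined")
    diff = q.mean - p.mean
    sol = np.linalg.solve(sq, np.column_stack([sp, diff]))
    val = 0.5 * (
        np.trace(sol[:, :n]) + diff @ sol[:, n] - n + logdet_q - _logdet(sp)
    )
    return _clamp_nonneg(val, "KL divergence")


def causal_strength(
    model: GaussianModel, q: TripleQuery, direction: str, *, strict: bool = False
) -> float:
    """Directed causal strength C_{X->Y} = D_KL(P || P_{X->Y}) (nats).

    Asymmetric in general: severing x->y and severing y->x give different
    interventional distributions.
    """
    names = [q.x, q.y, *q.z]
    sub = model.submodel(names)
    joint = GaussianModel(
        sub.variables, sub.mean, _prepare_cov(sub.covariance, strict)
    )
    return kl_gaussian(joint, interventional_model(model, q, direction, strict=strict))


# ---------------------------------------------------------------------------
# CMI2


def cmi2(model: GaussianModel, q: TripleQuery, *, strict: bool = False) -> float:
    """Conditional mutual inclusive information, closed Gaussian form.

    Both interventional distributions share the joint's mean, so each KL
    term needs only traces and log-determinants:

        CMI2 = ¼ [ tr(Σ̂₁⁻¹Σ) + tr(Σ̂₂⁻¹Σ)
                   + ln|Σ̂₁| + ln|Σ̂₂| − 2 ln|Σ| − 2n ],

    with Σ the joint covariance over (x, y, z), Σ̂₁ the x->y-severed and
    Σ̂₂ the y->x-severed covariance, and n = |z| + 2.  This is checked
    against :func:`cmi2_oracle` (the definitional route), which is
    authoritative should the two ever disagree.

    Requires a non-empty conditioning set; order-0 CMI2 is plain MI.
    """
    q.validate(model)
    if q.order == 0:
        raise InputError("cmi2 requires a non-empty conditioning set; use mi for order 0")
    cov = _prepare_cov(model.submodel([q.x, q.y, *q.z]).covariance, strict)
    n = cov.shape[0]
    z_idx = list(range(2, n))
    sev_xy = _sever_child(cov, child=1, parent=0, z_idx=z_idx)  # x->y removed
    sev_yx = _sever_child(cov, child=0, parent=1, z_idx=z_idx)  # y->x removed
    logdet = _logdet(cov)
    total = 0.0
    for sev in (sev_xy, sev_yx):
        total += np.trace(np.linalg.solve(sev, cov)) + _logdet(sev) - logdet - n
    return _clamp_nonneg(0.25 * total, "CMI2")


def cmi2_oracle(model: GaussianModel, q: TripleQuery, *, strict: bool = False) -> float:
    """CMI2 by its definition: the average of the two directed causal
    strengths, each computed through the interventional model and the
    generic Gaussian KL divergence.  Serves as the independent reference
    for the closed form in :func:`cmi2`."""
    return 0.5 * (
        causal_strength(model, q, "x->y", strict=strict)
        + causal_strength(model, q, "y->x", strict=strict)
    )


# ---------------------------------------------------------------------------
# partial correlation (baseline measure for the inference engine)


def partial_correlation(model: GaussianModel, q: TripleQuery, *, strict: bool = False) -> float:
    """Absolute partial correlation of (x, y) given z; plain |Pearson r|
    when z is empty.  Baseline association measure in the style of
    partial-correlation PC algorithms."""
    q.validate(model)
    names = [q.x, q.y, *q.z]
    cov = _prepare_cov(model.submodel(names).covariance, strict)
    if q.order == 0:
        denom = np.sqrt(cov[0, 0] * cov[1, 1])
        if denom <= 0:
            raise DegenerateModelError("zero variance in correlation")
        return float(abs(cov[0, 1]) / denom)
    prec = np.linalg.inv(cov)
    return float(abs(-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])))
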