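"""Voxelwise longitudinal morphometry with trajectory model selection.

The substrate is a panel of modulated tissue-volume maps: one 3D volume per
subject per session, two groups (trained vs. control), sessions at known
experimental days.  Per voxel and per candidate time course f(t) the model

    y_ij = b0 + b1*TIV_i + b2*group_i + b3*f(t_j) + b4*group_i*f(t_j)
           + u0_i + u1_i*f(t_j) + e_ij

is fit by maximum likelihood (not REML, so likelihoods are comparable
across fixed-effect structures), with a per-subject random intercept and
random slope on f(t).  The group-by-time interaction b4 carries the
learning effect; its two-sided Wald test feeds Benjamini-Hochberg FDR
across voxels, and per-shape AIC maps feed the preferred-model labeling
(a voxel is labeled with a shape only when it beats every alternative by
more than a configurable AIC margin).

Candidate time courses over the training horizon T, all anchored at
f(0) = 0 and bounded by |f| <= 1:

* linear       f(t) = t/T            (steady change)
* asymptotic   f(t) = 1 - (1-t/T)^2  (change then stabilization)
* quadratic    f(t) = 4 t(T-t)/T^2   (change then renormalization)

Decreases are handled through the sign of the interaction (the signed
two-sided test replaces fitting each shape's negative twin).

The mixed-model likelihood is profiled: for a given scaled random-effect
covariance D (parameterized by its log-Cholesky factor), the fixed effects
and residual variance have closed-form GLS/ML solutions via the Woodbury
identity on the 2x2 random-effect block, leaving a 3-parameter
optimization per voxel.  This is what makes whole-grid fits tractable;
the result is validated against brute-force likelihood maximization and
statsmodels MixedLM in the test suite.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from statsmodels.stats.multitest import multipletests

from .model_selection import TRAJECTORY_SHAPES, ModelFit, aicc

__all__ = [
    "SESSION_DAYS",
    "DEFAULT_VOXEL_SIZE_MM",
    "SubjectRecord",
    "VolumeSeries",
    "VoxelFit",
    "VoxelFitMaps",
    "TrajectoryLME",
    "InsufficientDataError",
    "trajectory_basis",
    "fit_voxel_lme",
    "voxelwise_maps",
    "fdr_bh",
    "preferred_model_map",
    "cluster_volume",
    "extract_voi",
    "ols_trajectory_fit",
    "subject_trajectory_aicc",
    "smooth_volume",
    "tpm_mask",
]

#: Experimental days of the six MRI sessions (baseline + five during training).
SESSION_DAYS: tuple[float, ...] = (0.0, 2.0, 6.0, 8.0, 10.0, 14.0)

#: Analysis grid resolution after resampling, mm isotropic.
DEFAULT_VOXEL_SIZE_MM = 0.08

#: AIC margin for the preferred-model labeling of voxels.
DEFAULT_PREFERRED_DELTA_AIC = 10.0


class InsufficientDataError(ValueError):
    """Too few observations for the requested fit."""


# ---------------------------------------------------------------------------
# Trajectory bases
# ---------------------------------------------------------------------------

def trajectory_basis(
    shape: str,
    t: float | np.ndarray,
    horizon: float = SESSION_DAYS[-1],
    sign: int = 1,
):
    """Evaluate a candidate time course f(t) on [0, horizon].

    All shapes satisfy f(0) = 0 and |f| <= 1.  ``sign=-1`` returns the
    opposite (decreasing) function.

    Raises
    ------
    ValueError
        For an unknown shape, nonpositive horizon, or t outside
        [0, horizon].
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    if sign not in (1, -1):
        raise ValueError(f"sign must be +1 or -1, got {sign}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > horizon):
        raise ValueError(f"t must lie in [0, {horizon}]")
    u = t_arr / horizon
    if shape == "linear":
        vals = u
    elif shape == "asymptotic":
        vals = 1.0 - (1.0 - u) ** 2
    elif shape == "quadratic":
        vals = 4.0 * u * (1.0 - u)
    else:
        raise ValueError(f"unknown trajectory shape {shape!r}")
    vals = sign * vals
    return float(vals) if np.isscalar(t) else vals


# ---------------------------------------------------------------------------
# Panel containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject metadata driving the unbalanced panel."""

    id: str
    group: str
    tiv: float
    days_present: tuple[float, ...] = SESSION_DAYS
    learning_rate: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("trained", "control"):
            raise ValueError(f"group must be 'trained' or 'control', got {self.group!r}")
        if not (self.tiv > 0):
            raise ValueError(f"TIV must be positive, got {self.tiv}")

    @property
    def is_trained(self) -> bool:
        return self.group == "trained"


@dataclass
class VolumeSeries:
    """Panel of voxel maps: data[subject, session, x, y, z].

    ``missing[s, t]`` marks subject-sessions absent from disk; their data
    slice is ignored by every fit.
    """

    data: np.ndarray
    voxel_size: float = DEFAULT_VOXEL_SIZE_MM
    session_days: tuple[float, ...] = SESSION_DAYS
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 5:
            raise ValueError(
                f"data must be 5-axis [subject, session, x, y, z], got {self.data.shape}"
            )
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        days = tuple(float(d) for d in self.session_days)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("session_days must be strictly increasing")
        self.session_days = days
        if self.data.shape[1] != len(days):
            raise ValueError("session axis does not match session_days")
        if self.missing is None:
            self.missing = np.zeros(self.data.shape[:2], dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.data.shape[:2]:
                raise ValueError("missing mask must be [subject, session]")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[2:]


# ---------------------------------------------------------------------------
# Profiled-ML linear mixed model
# ---------------------------------------------------------------------------

#: fixed effects: intercept, TIV (centered), group, f(t), group x f(t)
_FIXED_NAMES = ("intercept", "tiv", "group", "time", "group:time")
_IDX_INTERACTION = 4
#: parameters counted for AIC: 5 fixed + 3 random-effect covariance + residual
_K_LME = len(_FIXED_NAMES) + 3 + 1


@dataclass(frozen=True)
class VoxelFit:
    """Per-voxel mixed-model result for one trajectory shape."""

    shape: str
    beta: np.ndarray
    beta_se: np.ndarray
    log_likelihood: float
    n: int
    df_t: int
    k: int = _K_LME
    converged: bool = True
    degenerate: bool = False

    @property
    def beta3(self) -> float:
        """Group-by-time interaction estimate."""
        return float(self.beta[_IDX_INTERACTION])

    @property
    def p_interaction(self) -> float:
        """Two-sided Wald p-value for the interaction (1.0 if degenerate).

        The reference is a t distribution with ``n_subjects - 2`` degrees
        of freedom: the interaction contrasts mean slopes between two
        groups of subjects, so subjects (not observations) carry its
        information, and the normal reference is anti-conservative on
        small panels with ML variance estimates.
        """
        if self.degenerate or not self.converged:
            return 1.0
        se = self.beta_se[_IDX_INTERACTION]
        if not np.isfinite(se) or se <= 0:
            return 1.0
        z = self.beta[_IDX_INTERACTION] / se
        return float(2.0 * stats.t.sf(abs(z), self.df_t))

    @property
    def ci95_interaction(self) -> tuple[float, float]:
        half = stats.t.ppf(0.975, self.df_t) * self.beta_se[_IDX_INTERACTION]
        return (self.beta3 - half, self.beta3 + half)

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * self.k

    @property
    def aicc(self) -> float:
        return aicc(self.log_likelihood, self.k, self.n)

    def model_fit(self) -> ModelFit:
        return ModelFit(self.shape, self.log_likelihood, self.k, self.n)


class TrajectoryLME:
    """Reusable voxel fitter for one trajectory shape on a fixed panel.

    Precomputes every cross-product that does not involve the response, so
    fitting a voxel reduces to a 3-parameter profiled-likelihood
    optimization with 2x2 linear algebra (Woodbury identity on the
    random-effect block).  Subjects sharing a session-presence pattern are
    batched.
    """

    def __init__(
        self,
        subjects: Sequence[SubjectRecord],
        shape: str = "asymptotic",
        session_days: Sequence[float] = SESSION_DAYS,
        horizon: float | None = None,
    ) -> None:
        if len(subjects) < 4:
            raise InsufficientDataError("need at least 2 subjects per group")
        groups = {s.group for s in subjects}
        if groups != {"trained", "control"}:
            raise InsufficientDataError(
                f"need both trained and control subjects, got {sorted(groups)}"
            )
        self.shape = shape
        self.subjects = list(subjects)
        self.session_days = tuple(float(d) for d in session_days)
        self.horizon = float(horizon if horizon is not None else max(self.session_days))

        tiv_mean = float(np.mean([s.tiv for s in subjects]))
        day_index = {d: j for j, d in enumerate(self.session_days)}
        f_all = trajectory_basis(shape, np.array(self.session_days), self.horizon)

        # Group subjects by session-presence pattern; within a pattern the
        # random-effect design Z (and hence the Woodbury core) is shared.
        patterns: dict[tuple[int, ...], list[int]] = {}
        for i, s in enumerate(subjects):
            present = tuple(sorted(day_index[d] for d in s.days_present))
            if len(present) < 2:
                raise InsufficientDataError(
                    f"subject {s.id} has fewer than 2 sessions"
                )
            patterns.setdefault(present, []).append(i)

        self._blocks = []
        n_total = 0
        p = len(_FIXED_NAMES)
        for present, idxs in patterns.items():
            sess = np.array(present, dtype=int)
            f = f_all[sess]
            Z = np.column_stack([np.ones_like(f), f])  # (ni, 2)
            ni = len(sess)
            m = len(idxs)
            X = np.empty((m, ni, p))
            for a, i in enumerate(idxs):
                s = subjects[i]
                g = 1.0 if s.is_trained else 0.0
                X[a] = np.column_stack(
                    [np.ones(ni), np.full(ni, s.tiv - tiv_mean), np.full(ni, g), f, g * f]
                )
            XtZ = np.einsum("aip,iz->apz", X, Z)
            self._blocks.append(
                {
                    "subject_idx": np.array(idxs, dtype=int),
                    "sessions": sess,
                    "Z": Z,
                    "ZtZ": Z.T @ Z,
                    "X": X,
                    "XtX_sum": np.einsum("aip,aiq->pq", X, X),
                    "XtZ": XtZ,
                    # (m, p) slices of X'Z for the hand-rolled 2x2 algebra
                    "U0": np.ascontiguousarray(XtZ[:, :, 0]),
                    "U1": np.ascontiguousarray(XtZ[:, :, 1]),
                }
            )
            n_total += m * ni
        self.n_obs = n_total
        self.n_fixed = p
        self.k = _K_LME
        if n_total <= self.k + 1:
            raise InsufficientDataError(
                f"{n_total} observations cannot support k={self.k} parameters"
            )

    # -- likelihood machinery ------------------------------------------------

    @staticmethod
    def _theta_to_D(theta: np.ndarray) -> np.ndarray:
        """Log-Cholesky parameterization of the scaled RE covariance."""
        t0, t1, t2 = np.clip(theta, -12.0, 8.0)
        L = np.array([[math.exp(t0), 0.0], [t1, math.exp(t2)]])
        return L @ L.T

    def _profile(self, theta: np.ndarray, blocks_y):
        """Profiled -2 log-likelihood and GLS pieces at one theta.

        All random-effect algebra is 2x2 and hand-rolled (this is the hot
        path of the voxelwise sweep): with D the scaled RE covariance,
        A = I + Z'Z D gives log|I + Z D Z'| = log|A| and the Woodbury
        correction kernel K = D A^{-1} = (D^{-1} + Z'Z)^{-1}.
        """
        D = self._theta_to_D(theta)
        d00, d01, d11 = D[0, 0], D[0, 1], D[1, 1]
        p = self.n_fixed
        XtViX = np.zeros((p, p))
        XtViy = np.zeros(p)
        ytViy = 0.0
        logdet = 0.0
        for blk, (Xty, Zty, yty) in zip(self._blocks, blocks_y):
            ZtZ = blk["ZtZ"]
            z00, z01, z11 = ZtZ[0, 0], ZtZ[0, 1], ZtZ[1, 1]
            a00 = 1.0 + z00 * d00 + z01 * d01
            a01 = z00 * d01 + z01 * d11
            a10 = z01 * d00 + z11 * d01
            a11 = 1.0 + z01 * d01 + z11 * d11
            det_a = a00 * a11 - a01 * a10
            if det_a <= 0:
                return np.inf, None
            # K = D @ A^{-1}, symmetrized against roundoff
            i00, i01, i10, i11 = a11 / det_a, -a01 / det_a, -a10 / det_a, a00 / det_a
            k00 = d00 * i00 + d01 * i10
            k11 = d01 * i01 + d11 * i11
            k01 = 0.5 * ((d00 * i01 + d01 * i11) + (d01 * i00 + d11 * i10))
            m = blk["X"].shape[0]
            logdet += m * math.log(det_a)
            U0, U1 = blk["U0"], blk["U1"]  # (m, p)
            zy0, zy1 = Zty[:, 0], Zty[:, 1]
            W0 = U0 * k00 + U1 * k01
            W1 = U0 * k01 + U1 * k11
            XtViX += blk["XtX_sum"] - (W0.T @ U0 + W1.T @ U1)
            v0 = zy0 * k00 + zy1 * k01
            v1 = zy0 * k01 + zy1 * k11
            XtViy += Xty.sum(axis=0) - (v0 @ U0 + v1 @ U1)
            ytViy += yty.sum() - float(zy0 @ v0 + zy1 @ v1)
        try:
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            return np.inf, None
        rss = ytViy - XtViy @ beta
        n = self.n_obs
        if rss <= 0 or not np.isfinite(rss):
            return np.inf, None
        sigma2 = rss / n
        neg2ll = n * math.log(2.0 * math.pi * sigma2) + logdet + n
        return neg2ll, (beta, sigma2, XtViX)

    def _response_blocks(self, y: np.ndarray):
        """Per-pattern response cross-products for one voxel.

        ``y`` is [subject, session] with NaN allowed only on missing
        sessions.
        """
        blocks_y = []
        for blk in self._blocks:
            ysub = y[np.ix_(blk["subject_idx"], blk["sessions"])]  # (m, ni)
            if np.any(~np.isfinite(ysub)):
                raise ValueError(
                    "non-finite response on a session marked present"
                )
            Z = blk["Z"]
            Xty = np.einsum("aip,ai->ap", blk["X"], ysub)
            Zty = ysub @ Z
            yty = np.einsum("ai,ai->a", ysub, ysub)
            blocks_y.append((Xty, Zty, yty))
        return blocks_y

    def fit(self, y: np.ndarray, theta0: np.ndarray | None = None) -> VoxelFit:
        """Maximum-likelihood fit of one voxel's panel.

        ``theta0`` warm-starts the variance-component search (useful when
        sweeping spatially smooth maps).
        """
        y = np.asarray(y, dtype=float)
        values = np.concatenate(
            [y[np.ix_(b["subject_idx"], b["sessions"])].ravel() for b in self._blocks]
        )
        p = self.n_fixed
        df_t = len(self.subjects) - 2
        if np.var(values) < 1e-24:
            return VoxelFit(
                shape=self.shape,
                beta=np.zeros(p),
                beta_se=np.full(p, np.nan),
                log_likelihood=-np.inf,
                n=self.n_obs,
                df_t=df_t,
                converged=False,
                degenerate=True,
            )
        blocks_y = self._response_blocks(y)

        # perfect (zero-residual) fits: the ML residual variance collapses
        # and the likelihood diverges; report the exact OLS coefficients
        # and flag the voxel degenerate.
        X_all = np.vstack([b["X"].reshape(-1, p) for b in self._blocks])
        y_all = np.concatenate(
            [y[np.ix_(b["subject_idx"], b["sessions"])].ravel() for b in self._blocks]
        )
        ols_beta, _, _, _ = np.linalg.lstsq(X_all, y_all, rcond=None)
        ols_rss = float(np.sum((y_all - X_all @ ols_beta) ** 2))
        if ols_rss < 1e-18 * max(1.0, float(np.var(values)) * self.n_obs):
            return VoxelFit(
                shape=self.shape,
                beta=ols_beta,
                beta_se=np.zeros(p),
                log_likelihood=np.inf,
                n=self.n_obs,
                df_t=df_t,
                converged=True,
                degenerate=True,
            )

        def objective(theta):
            return self._profile(theta, blocks_y)[0]

        starts = [np.array([-2.0, 0.0, -2.0])]
        if theta0 is not None:
            starts.insert(0, np.asarray(theta0, dtype=float))
        best = None
        for x0 in starts:
            res = optimize.minimize(
                objective,
                x0,
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400},
            )
            if best is None or res.fun < best.fun:
                best = res
            if best.success and best.fun < np.inf:
                break
        neg2ll, pieces = self._profile(best.x, blocks_y)
        if pieces is None or not np.isfinite(neg2ll):
            return VoxelFit(
                shape=self.shape,
                beta=np.full(p, np.nan),
                beta_se=np.full(p, np.nan),
                log_likelihood=-np.inf,
                n=self.n_obs,
                df_t=df_t,
                converged=False,
            )
        beta, sigma2, XtViX = pieces
        cov = sigma2 * np.linalg.inv(XtViX)
        fit = VoxelFit(
            shape=self.shape,
            beta=beta,
            beta_se=np.sqrt(np.diag(cov)),
            log_likelihood=-0.5 * neg2ll,
            n=self.n_obs,
            df_t=df_t,
            converged=bool(best.success or np.isfinite(neg2ll)),
        )
        # stash the optimum for warm-starting neighbors
        object.__setattr__(fit, "theta", best.x)
        return fit


def fit_voxel_lme(
    y: np.ndarray,
    subjects: Sequence[SubjectRecord],
    shape: str = "asymptotic",
    session_days: Sequence[float] = SESSION_DAYS,
    horizon: float | None = None,
) -> VoxelFit:
    """Fit one voxel's longitudinal panel with a single trajectory shape.

    ``y`` is a [subject, session] array; entries on sessions a subject is
    not recorded for (per ``SubjectRecord.days_present``) are ignored and
    may be NaN.  See :class:`TrajectoryLME` for the model; use that class
    directly when fitting many voxels on the same panel.
    """
    return TrajectoryLME(subjects, shape, session_days, horizon).fit(y)


# ---------------------------------------------------------------------------
# Voxelwise maps
# ---------------------------------------------------------------------------

@dataclass
class VoxelFitMaps:
    """Statistical-map product of the voxelwise analysis.

    Per-shape 3D maps (NaN outside the analysis mask / on failed voxels)
    of the interaction estimate, its Wald p, AIC and AICc; per-shape,
    per-sign FDR-significant masks; and the preferred-model label map
    (0 = unlabeled, 1-based index into ``shapes``).
    """

    shapes: tuple[str, ...]
    mask: np.ndarray
    beta3: dict[str, np.ndarray]
    pvalue: dict[str, np.ndarray]
    aic: dict[str, np.ndarray]
    aicc: dict[str, np.ndarray]
    significant: dict[tuple[str, str], np.ndarray]
    fdr_threshold: dict[str, float]
    preferred: np.ndarray
    q: float
    voxel_size: float
    qc: pd.DataFrame = field(default_factory=pd.DataFrame)

    def significant_count(self, shape: str, sign: str) -> int:
        return int(self.significant[(shape, sign)].sum())


def fdr_bh(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up over a family of p-values.

    Returns the rejection mask and the adaptive threshold (largest
    rejected p, 0.0 when nothing is rejected).  NaN entries are never
    rejected and do not count toward the family size.
    """
    if not (0 < q < 1):
        raise ValueError(f"q must be in (0, 1), got {q}")
    p = np.asarray(pvalues, dtype=float)
    flat = p.ravel()
    out = np.zeros(flat.shape, dtype=bool)
    finite = np.isfinite(flat)
    if finite.sum() == 0:
        return out.reshape(p.shape), 0.0
    vals = flat[finite]
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(vals, alpha=q, method="fdr_bh")
    out[finite] = reject
    threshold = float(vals[reject].max()) if reject.any() else 0.0
    return out.reshape(p.shape), threshold


def preferred_model_map(
    aic_maps: Mapping[str, np.ndarray],
    delta: float = DEFAULT_PREFERRED_DELTA_AIC,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Label each voxel with the decisively best shape, if any.

    A voxel gets label ``i+1`` for shape ``shapes[i]`` iff that shape's
    AIC plus ``delta`` is below every other shape's AIC; otherwise 0.
    NaN AICs count as infinitely bad.
    """
    shapes = tuple(aic_maps)
    if len(shapes) < 2:
        raise ValueError("need at least two AIC maps")
    arrs = [np.asarray(aic_maps[s], dtype=float) for s in shapes]
    ref_shape = arrs[0].shape
    if any(a.shape != ref_shape for a in arrs):
        raise ValueError("AIC maps are not aligned (mismatched shapes)")
    stack = np.stack([np.where(np.isfinite(a), a, np.inf) for a in arrs])
    order = np.sort(stack, axis=0)
    best, second = order[0], order[1]
    winner = np.argmin(stack, axis=0)
    labeled = np.isfinite(best) & (best + delta < second)
    labels = np.where(labeled, winner + 1, 0).astype(np.int16)
    return labels, shapes


def voxelwise_maps(
    series: VolumeSeries,
    subjects: Sequence[SubjectRecord],
    mask: np.ndarray,
    shapes: Sequence[str] = TRAJECTORY_SHAPES,
    q: float = 0.05,
    delta_aic: float = DEFAULT_PREFERRED_DELTA_AIC,
    horizon: float | None = None,
) -> VoxelFitMaps:
    """Mass-univariate mixed-model analysis over an analysis mask.

    Fits every in-mask voxel with every candidate shape, applies BH-FDR
    across in-mask voxels per shape, splits significant voxels by the
    sign of the interaction, and labels voxels whose best shape wins by
    more than ``delta_aic``.  Degenerate or non-converged voxels are
    logged in ``qc`` and excluded from the maps (NaN p-value, never
    significant).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.grid_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match grid {series.grid_shape}"
        )
    if not mask.any():
        raise ValueError("analysis mask is empty")
    if len(subjects) != series.n_subjects:
        raise ValueError("subject metadata does not match the series")

    coords = np.argwhere(mask)
    grid = series.grid_shape
    beta3, pval, aic_m, aicc_m = {}, {}, {}, {}
    sig: dict[tuple[str, str], np.ndarray] = {}
    thresholds: dict[str, float] = {}
    qc_rows = []

    for shape in shapes:
        fitter = TrajectoryLME(subjects, shape, series.session_days, horizon)
        b3 = np.full(grid, np.nan)
        pv = np.full(grid, np.nan)
        am = np.full(grid, np.nan)
        cm = np.full(grid, np.nan)
        theta = None
        n_bad = 0
        for (ix, iy, iz) in coords:
            fit = fitter.fit(series.data[:, :, ix, iy, iz], theta0=theta)
            if fit.degenerate or not fit.converged:
                n_bad += 1
                qc_rows.append(
                    {
                        "shape": shape,
                        "voxel": (int(ix), int(iy), int(iz)),
                        "reason": "degenerate" if fit.degenerate else "non-converged",
                    }
                )
                continue
            theta = getattr(fit, "theta", None)
            b3[ix, iy, iz] = fit.beta3
            pv[ix, iy, iz] = fit.p_interaction
            am[ix, iy, iz] = fit.aic
            cm[ix, iy, iz] = fit.aicc
        beta3[shape], pval[shape], aic_m[shape], aicc_m[shape] = b3, pv, am, cm
        rejected, thr = fdr_bh(pv[mask], q)
        thresholds[shape] = thr
        sig_map = np.zeros(grid, dtype=bool)
        sig_map[mask] = rejected
        sig[(shape, "increase")] = sig_map & (b3 > 0)
        sig[(shape, "decrease")] = sig_map & (b3 < 0)

    if len(shapes) >= 2:
        preferred, _ = preferred_model_map(
            {s: aic_m[s] for s in shapes}, delta=delta_aic
        )
    else:
        preferred = np.zeros(grid, dtype=np.int16)
    return VoxelFitMaps(
        shapes=tuple(shapes),
        mask=mask,
        beta3=beta3,
        pvalue=pval,
        aic=aic_m,
        aicc=aicc_m,
        significant=sig,
        fdr_threshold=thresholds,
        preferred=preferred,
        q=q,
        voxel_size=series.voxel_size,
        qc=pd.DataFrame(qc_rows),
    )


# ---------------------------------------------------------------------------
# Cluster volumes, VOI extraction, per-subject trajectory fits
# ---------------------------------------------------------------------------

def cluster_volume(n_voxels: int, voxel_size: float = DEFAULT_VOXEL_SIZE_MM) -> float:
    """Convert a significant-voxel count to mm^3 (reported to 2 decimals)."""
    if n_voxels < 0:
        raise ValueError(f"voxel count must be nonnegative, got {n_voxels}")
    if voxel_size <= 0:
        raise ValueError(f"voxel size must be positive, got {voxel_size}")
    return round(n_voxels * voxel_size**3, 2)


def extract_voi(
    series: VolumeSeries,
    voi_mask: np.ndarray,
    subjects: Sequence[SubjectRecord],
) -> pd.DataFrame:
    """Per-subject, per-session VOI means normalized to the control group.

    Returns a DataFrame indexed by subject id with one column per session
    day: mean over in-VOI voxels divided by the same-session mean over
    control subjects.  Missing sessions are NaN.
    """
    voi_mask = np.asarray(voi_mask, dtype=bool)
    if voi_mask.shape != series.grid_shape:
        raise ValueError("VOI mask does not match the series grid")
    if not voi_mask.any():
        raise ValueError("VOI mask is empty")
    controls = [i for i, s in enumerate(subjects) if not s.is_trained]
    if not controls:
        raise ValueError("need at least one control subject to normalize")
    means = series.data[:, :, voi_mask].mean(axis=2)  # (subject, session)
    means = np.where(series.missing, np.nan, means)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        control_mean = np.nanmean(means[controls], axis=0)
    if np.any(~np.isfinite(control_mean)) or np.any(control_mean == 0):
        raise ValueError("control-group mean is zero or undefined for some session")
    normalized = means / control_mean
    return pd.DataFrame(
        normalized,
        index=[s.id for s in subjects],
        columns=list(series.session_days),
    )


def ols_trajectory_fit(
    days: Sequence[float],
    values: Sequence[float],
    shape: str,
    horizon: float | None = None,
) -> ModelFit:
    """OLS fit of one trajectory shape to a single series.

    The model is ``y = a + b * f(t)``; the Gaussian ML log-likelihood uses
    the ML variance (RSS/n), and k = 3 counts intercept, shape
    coefficient, and residual variance.
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values)
    days, values = days[keep], values[keep]
    n = len(values)
    if n < 4:
        raise InsufficientDataError(f"need >= 4 observations, got {n}")
    T = float(horizon if horizon is not None else days.max())
    f = trajectory_basis(shape, days, T)
    X = np.column_stack([np.ones(n), f])
    coef, _, _, _ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ coef
    rss = float(resid @ resid)
    sigma2 = max(rss / n, 1e-300)
    loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    return ModelFit(name=shape, log_likelihood=loglik, k=3, n=n)


def subject_trajectory_aicc(
    days: Sequence[float],
    values: Sequence[float],
    shapes: Sequence[str] = ("linear", "asymptotic"),
    horizon: float | None = None,
) -> dict[str, float]:
    """Per-subject AICc of each candidate shape fit to a VOI trajectory.

    Lower asymptotic AICc means a more asymptotic-like trajectory; pairing
    these values with learning rates across animals yields the
    rate-vs-plateau correlation.
    """
    return {
        s: ols_trajectory_fit(days, values, s, horizon).aicc for s in shapes
    }


# ---------------------------------------------------------------------------
# Preprocessing utilities
# ---------------------------------------------------------------------------

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def smooth_volume(
    volume: np.ndarray, fwhm: float, voxel_size: float = DEFAULT_VOXEL_SIZE_MM
) -> np.ndarray:
    """Isotropic Gaussian smoothing specified by FWHM in mm.

    ``sigma = fwhm / (2 sqrt(2 ln 2))`` converted to voxels; reflective
    boundary handling preserves the total tissue amount.  ``fwhm=0`` is
    the identity.
    """
    if fwhm < 0:
        raise ValueError(f"fwhm must be nonnegative, got {fwhm}")
    volume = np.asarray(volume, dtype=float)
    if fwhm == 0:
        return volume.copy()
    sigma_vox = fwhm / _FWHM_TO_SIGMA / voxel_size
    return ndimage.gaussian_filter(volume, sigma=sigma_vox, mode="reflect")


def tpm_mask(probability_map: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Binary mask from a tissue-probability map (inclusive threshold)."""
    p = np.asarray(probability_map, dtype=float)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("tissue probabilities must lie in [0, 1]")
    return p >= threshold
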