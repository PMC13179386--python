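"""First-level robust regression maps and group one-sample statistics.

At the subject level, single-trial voltages at every electrode × time cell
are regressed on the task design with iteratively reweighted least squares
(Tukey bisquare, tuning 4.685, MAD scale), which is insensitive to outlier
trials and heteroskedastic noise. The fits are vectorised across the whole
electrode × time grid.

At the group level, the per-subject b-values of a regressor are compared
against zero with two-tailed one-sample t-tests (df = n − 1) at every cell,
corrected with the Benjamini–Hochberg false-discovery-rate step-up over all
cells, and summarised by peak statistics (beta, t, p, critical p, a
confidence interval at the 100×(1 − critical p)% level, and Hedge's g).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import DesignMatrix
from .epochs import EpochSet
from .exceptions import DataError, DesignError, FormatError, ParameterError

__all__ = [
    "irls_fit",
    "BetaMap",
    "SingleTrialRegression",
    "fit_subject_maps",
    "write_betamap",
    "read_betamap",
    "GroupStatMap",
    "GroupOneSample",
    "group_onesample_map",
    "fdr_bh",
    "PeakReport",
    "find_peak",
    "hedges_g",
    "score_questionnaire",
]

BISQUARE_TUNING = 4.685
IRLS_TOL = 1e-6
IRLS_MAX_ITER = 50
_MAD_NORM = 0.6745


def _check_design(X: np.ndarray, names) -> None:
    n, p = X.shape
    if n < p + 5:
        raise DesignError(f"need at least {p + 5} rows for {p} columns, got {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the dependent columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(X, pivoting=True, mode="economic")
        dep = sorted(names[j] for j in piv[rank:])
        raise DesignError(f"design is rank deficient; dependent column(s): {dep}")


def _irls_grid(Y: np.ndarray, X: np.ndarray, tuning=BISQUARE_TUNING,
               tol=IRLS_TOL, max_iter=IRLS_MAX_ITER):
    """Vectorised IRLS over many cells sharing one design.

    Y : (n, m) observations for m cells; X : (n, p).
    Returns (b (p, m), weights (n, m), iterations (m,), converged (m,)).
    """
    n, p = X.shape
    m = Y.shape[1]
    b = np.linalg.lstsq(X, Y, rcond=None)[0]  # OLS start
    w_out = np.ones((n, m))
    iterations = np.zeros(m, int)
    converged = np.zeros(m, bool)
    y_mag = max(1.0, float(np.abs(Y).max())) if Y.size else 1.0
    pairs = (X[:, :, None] * X[:, None, :]).reshape(n, p * p)  # X_i * X_j per row
    active = np.arange(m)
    for it in range(1, max_iter + 1):
        Ya = Y[:, active]
        ba = b[:, active]
        resid = Ya - X @ ba
        scale = np.median(np.abs(resid), axis=0) / _MAD_NORM  # MAD about zero
        exact = scale <= 1e-10 * y_mag
        scale = np.where(exact, 1.0, scale)
        u = resid / (tuning * scale)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        w[:, exact] = 1.0
        # per-cell weighted normal equations: two GEMMs + batched 3x3 solves
        A = (pairs.T @ w).T.reshape(active.size, p, p)
        c = (X.T @ (w * Ya)).T  # (m_a, p)
        try:
            b_new = np.linalg.solve(A, c[:, :, None])[:, :, 0].T
        except np.linalg.LinAlgError:
            b_new = np.empty_like(ba)
            for j in range(active.size):
                b_new[:, j] = np.linalg.lstsq(A[j], c[j], rcond=None)[0]
        delta = np.abs(b_new - ba).max(axis=0)
        b[:, active] = b_new
        w_out[:, active] = w
        iterations[active] = it
        done = (delta < tol) | exact
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break
    return b, w_out, iterations, converged


def irls_fit(y, X, tuning=BISQUARE_TUNING, tol=IRLS_TOL, max_iter=IRLS_MAX_ITER):
    """Robust regression of one cell's trial values on the design.

    Iteratively reweighted least squares with Tukey bisquare weights
    (tuning 4.685) and scale = MAD of residuals / 0.6745 recomputed each
    iteration; convergence when the largest coefficient change drops below
    ``tol`` (default 1e−6) or after ``max_iter`` (default 50) iterations.

    Returns ``(b, diagnostics)`` with diagnostics holding the final
    robustness weights, the iteration count and a convergence flag.
    """
    if isinstance(X, DesignMatrix):
        names, Xa = X.names, X.X
    else:
        Xa = np.asarray(X, float)
        names = [f"x{j}" for j in range(Xa.shape[1])]
    y = np.asarray(y, float)
    _check_design(Xa, names)
    b, w, iters, conv = _irls_grid(y[:, None], Xa, tuning, tol, max_iter)
    return b[:, 0], {
        "weights": w[:, 0],
        "iterations": int(iters[0]),
        "converged": bool(conv[0]),
    }


# ---------------------------------------------------------------------------
# subject-level maps
# ---------------------------------------------------------------------------

@dataclass
class BetaMap:
    """Per-subject regression weights on the electrode × time grid.

    ``b`` has shape (n_channels, n_times, n_regressors), in µV per
    regressor unit; ``iterations`` and ``converged`` hold the per-cell IRLS
    diagnostics.
    """

    b: np.ndarray
    channels: list[str]
    times: np.ndarray
    regressors: list[str]
    subject: str | None = None
    task: str | None = None
    iterations: np.ndarray | None = None
    converged: np.ndarray | None = None

    def __post_init__(self):
        self.b = np.asarray(self.b, float)
        self.times = np.asarray(self.times, float)
        if self.b.shape != (len(self.channels), self.times.size, len(self.regressors)):
            raise DataError(
                f"b shape {self.b.shape} inconsistent with "
                f"{len(self.channels)} channels x {self.times.size} times x "
                f"{len(self.regressors)} regressors"
            )
        if self.iterations is None:
            self.iterations = np.zeros(self.b.shape[:2], int)
        if self.converged is None:
            self.converged = np.ones(self.b.shape[:2], bool)

    def regressor_index(self, name: str) -> int:
        try:
            return self.regressors.index(name)
        except ValueError:
            raise DataError(f"regressor {name!r} not in {self.regressors}") from None

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise DataError(f"channel {name!r} not in montage") from None


class SingleTrialRegression:
    """Model object: robust single-trial regression of an epoch grid.

    Parameters
    ----------
    epochs : EpochSet
        Preprocessed (smoothed, window-selected) epochs.
    design : DesignMatrix
        Task design; its ``rows`` select the retained trials.
    """

    def __init__(self, epochs: EpochSet, design: DesignMatrix):
        if design.rows.size and design.rows.max() >= epochs.n_trials:
            raise DataError(
                f"design row index {design.rows.max()} exceeds {epochs.n_trials} trials"
            )
        self.epochs = epochs
        self.design = design

    def fit(self, tuning=BISQUARE_TUNING, tol=IRLS_TOL, max_iter=IRLS_MAX_ITER) -> BetaMap:
        ep, d = self.epochs, self.design
        _check_design(d.X, d.names)
        Y = ep.data[d.rows].reshape(d.n_rows, -1)
        b, _, iters, conv = _irls_grid(Y, d.X, tuning, tol, max_iter)
        grid = (ep.n_channels, ep.n_times)
        return BetaMap(
            b.T.reshape(grid + (d.n_cols,)),
            list(ep.channels),
            ep.times.copy(),
            list(d.names),
            subject=ep.provenance.get("subject"),
            task=ep.provenance.get("task"),
            iterations=iters.reshape(grid),
            converged=conv.reshape(grid),
        )


def fit_subject_maps(epochs: EpochSet, design: DesignMatrix, **kwargs) -> BetaMap:
    """Fit the robust regression independently at every (channel, time)."""
    return SingleTrialRegression(epochs, design).fit(**kwargs)


def write_betamap(bmap: BetaMap, path) -> None:
    """Persist a BetaMap bundle (manifest + float32 b + diagnostics)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "kind": "betamap-bundle",
        "shape": list(bmap.b.shape),
        "dtype": "<f4",
        "channels": bmap.channels,
        "times_ms": [float(t) for t in bmap.times],
        "regressors": bmap.regressors,
        "subject": bmap.subject,
        "task": bmap.task,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    bmap.b.astype("<f4").tofile(path / "b.f32")
    bmap.iterations.astype("<i4").tofile(path / "iterations.i32")
    bmap.converged.astype("u1").tofile(path / "converged.u8")


def read_betamap(path) -> BetaMap:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    shape = tuple(manifest["shape"])
    raw = np.fromfile(path / "b.f32", dtype="<f4")
    if raw.size != int(np.prod(shape)):
        raise FormatError(
            f"b.f32 holds {raw.size} values but manifest shape {shape} needs {int(np.prod(shape))}"
        )
    grid = shape[:2]
    return BetaMap(
        raw.reshape(shape).astype(float),
        manifest["channels"],
        np.asarray(manifest["times_ms"], float),
        manifest["regressors"],
        subject=manifest.get("subject"),
        task=manifest.get("task"),
        iterations=np.fromfile(path / "iterations.i32", dtype="<i4").reshape(grid),
        converged=np.fromfile(path / "converged.u8", dtype="u1").reshape(grid).astype(bool),
    )


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def fdr_bh(pvals, alpha: float):
    """Benjamini–Hochberg step-up over a flat collection of p-values.

    Returns ``(reject flags, critical_p)`` where ``critical_p`` is the
    largest p-value among the rejected tests (0 if none are rejected).
    """
    p = np.asarray(pvals, float).ravel()
    if p.size == 0:
        raise ParameterError("empty p-value collection")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    reject = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    critical_p = float(p[reject].max()) if reject.any() else 0.0
    return reject, critical_p


@dataclass
class GroupStatMap:
    """Group-level one-sample statistics on the electrode × time grid."""

    term: str
    channels: list[str]
    times: np.ndarray
    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int
    alpha: float
    critical_p: float
    significant: np.ndarray
    n_subjects: int = 0

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise DataError(f"channel {name!r} not in montage") from None

    def find_peak(self, channels, window, polarity="positive") -> "PeakReport":
        return find_peak(self, channels, window, polarity)

    def summary(self) -> str:
        n_sig = int(self.significant.sum())
        lines = [
            f"Group one-sample t-map: term {self.term!r}",
            f"  subjects: {self.n_subjects} (df = {self.df})",
            f"  grid: {len(self.channels)} channels x {self.times.size} time points "
            f"= {self.beta.size} tests",
            f"  two-tailed alpha = {self.alpha}, BH-FDR critical p = {self.critical_p:.4g}",
            f"  significant cells: {n_sig} ({100 * n_sig / self.beta.size:.1f}%)",
        ]
        return "\n".join(lines)


class GroupOneSample:
    """Model object: one-sample t-map of per-subject b-values vs zero."""

    def __init__(self, maps: list[BetaMap], regressor: str):
        if len(maps) < 3:
            raise DataError(f"need at least 3 subjects, got {len(maps)}")
        ref = maps[0]
        for m in maps[1:]:
            if (
                m.channels != ref.channels
                or m.times.size != ref.times.size
                or not np.allclose(m.times, ref.times)
                or m.regressors != ref.regressors
            ):
                raise DataError(
                    f"subject grids differ (subject {m.subject!r} vs {ref.subject!r})"
                )
        self.maps = maps
        self.regressor = regressor
        self._stack = np.stack([m.b[:, :, ref.regressor_index(regressor)] for m in maps])

    def fit(self, alpha: float = 0.025) -> GroupStatMap:
        b = self._stack
        n = b.shape[0]
        mean = b.mean(axis=0)
        sd = b.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        t = np.where(sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
        df = n - 1
        p = np.where(np.isinf(t), 0.0, 2 * stats.t.sf(np.abs(np.where(np.isinf(t), 0, t)), df))
        p = np.where((sd == 0) & (mean == 0), 1.0, p)
        reject, critical_p = fdr_bh(p.ravel(), alpha)
        ref = self.maps[0]
        return GroupStatMap(
            term=self.regressor,
            channels=list(ref.channels),
            times=ref.times.copy(),
            beta=mean,
            t=t,
            p=p,
            df=df,
            alpha=alpha,
            critical_p=critical_p,
            significant=reject.reshape(p.shape),
            n_subjects=n,
        )


def group_onesample_map(maps: list[BetaMap], regressor: str, alpha: float = 0.025) -> GroupStatMap:
    """Two-tailed one-sample t-tests of b against zero at every cell, with
    BH-FDR over all channels × time points."""
    return GroupOneSample(maps, regressor).fit(alpha)


# ---------------------------------------------------------------------------
# peaks and effect sizes
# ---------------------------------------------------------------------------

def hedges_g(t: float, n: int) -> float:
    """One-sample Hedge's g from a t statistic: g = J · t/√n with the
    small-sample correction J = 1 − 3 / (4(n−1) − 1)."""
    if n < 2:
        raise ParameterError(f"need n >= 2 subjects, got {n}")
    j = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
    return j * t / np.sqrt(n)


@dataclass
class PeakReport:
    """Peak cell of a group map within a spatiotemporal search region."""

    found: bool
    term: str
    electrode: str | None = None
    time_ms: float | None = None
    beta: float | None = None
    t: float | None = None
    df: int | None = None
    p: float | None = None
    critical_p: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    ci_level: float | None = None  # confidence level in percent
    g: float | None = None

    def row(self) -> dict:
        """Peak-table row (Electrode, Time, t, p, critical p, CI, g)."""
        return {
            "term": self.term,
            "electrode": self.electrode,
            "time_ms": self.time_ms,
            "beta": self.beta,
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "critical_p": self.critical_p,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_level_pct": self.ci_level,
            "g": self.g,
        }


def find_peak(gmap: GroupStatMap, channels, window, polarity: str = "positive") -> PeakReport:
    """Locate the maximal-|t| FDR-significant cell in an ROI × time window.

    ``polarity`` restricts the sign of t ('positive', 'negative' or 'any').
    Ties break toward the earlier time point, then montage order. When the
    region contains no significant cell an explicit not-found report is
    returned. The confidence interval of the group beta is computed at the
    100×(1 − critical p)% level.
    """
    if polarity not in ("positive", "negative", "any"):
        raise ParameterError(f"polarity must be positive|negative|any, got {polarity!r}")
    ch_idx = [gmap.channel_index(c) for c in channels]
    if not ch_idx:
        raise ParameterError("empty ROI")
    lo, hi = float(window[0]), float(window[1])
    t_mask = (gmap.times >= lo - 1e-9) & (gmap.times <= hi + 1e-9)
    if not t_mask.any():
        raise ParameterError(f"window [{lo}, {hi}] contains no samples")
    cand = np.zeros(gmap.t.shape, bool)
    cand[np.ix_(ch_idx, np.nonzero(t_mask)[0])] = True
    cand &= gmap.significant
    if polarity == "positive":
        cand &= gmap.t > 0
    elif polarity == "negative":
        cand &= gmap.t < 0
    if not cand.any():
        return PeakReport(found=False, term=gmap.term)

    ci, ti = np.nonzero(cand)
    order = np.lexsort((ci, gmap.times[ti], -np.abs(gmap.t[ci, ti])))
    c, tt = ci[order[0]], ti[order[0]]
    beta, tval, p = float(gmap.beta[c, tt]), float(gmap.t[c, tt]), float(gmap.p[c, tt])
    n = gmap.df + 1
    if np.isinf(tval):
        lo_ci = hi_ci = beta
    else:
        se = beta / tval if tval != 0 else np.nan
        tcrit = stats.t.ppf(1 - gmap.critical_p / 2, gmap.df)
        lo_ci, hi_ci = beta - tcrit * abs(se), beta + tcrit * abs(se)
    return PeakReport(
        found=True,
        term=gmap.term,
        electrode=gmap.channels[c],
        time_ms=float(gmap.times[tt]),
        beta=beta,
        t=tval,
        df=gmap.df,
        p=p,
        critical_p=gmap.critical_p,
        ci_low=float(lo_ci),
        ci_high=float(hi_ci),
        ci_level=100.0 * (1 - gmap.critical_p),
        g=float(hedges_g(tval, n)) if np.isfinite(tval) else float(np.sign(tval) * np.inf),
    )


# ---------------------------------------------------------------------------
# questionnaire scoring
# ---------------------------------------------------------------------------

_SCALES = {"nu": (12, 1, 4), "ocir": (18, 0, 4)}


def score_questionnaire(items, scale: str) -> int:
    """Sum score for a questionnaire scale.

    ``nu``: 12 negative-urgency items, each 1–4 (sum 12–48).
    ``ocir``: 18 OCI-R items, each 0–4 (sum 0–72).
    """
    if scale not in _SCALES:
        raise ParameterError(f"scale must be one of {sorted(_SCALES)}, got {scale!r}")
    n_items, lo, hi = _SCALES[scale]
    items = np.asarray(items)
    if items.size != n_items:
        raise DataError(f"{scale} needs {n_items} items, got {items.size}")
    bad = np.nonzero((items < lo) | (items > hi) | (items != np.floor(items)))[0]
    if bad.size:
        raise DataError(
            f"item {int(bad[0])} value {items[bad[0]]} outside {scale} range [{lo}, {hi}]"
        )
    return int(items.sum())
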