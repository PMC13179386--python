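"""Second-level moderated brain–brain regression.

At every electrode × time cell, the per-subject first-level b of an
inhibition contrast is regressed on a windowed feedback-effect score and on
its product with a centred trait moderator:

    b = β0 + β1 · x_c + β2 · (x_c · m_c) + error

where x_c and m_c are the demeaned feedback score and moderator. By
default no moderator main effect is included (a flag adds one). Johnson–Neyman analysis then solves, in closed form, for the
moderator values at which the simple slope β1 + β2·m_c crosses the
two-sided significance threshold, yielding regions of significance in raw
moderator units. Maps are reported masked at an uncorrected p threshold
(no second-level FDR), and traits can be residualised on one another to
isolate variance unique to each construct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, DesignError, ParameterError
from .firstlevel import BetaMap

__all__ = [
    "WindowScore",
    "window_score",
    "ModerationFit",
    "ModeratedBrainRegression",
    "fit_moderated_map",
    "mask_map",
    "JNResult",
    "jn_points",
    "residualize",
]


@dataclass
class WindowScore:
    """Mean first-level b over a named electrode and ms window."""

    subject: str | None
    value: float
    component: str


def window_score(
    bmap: BetaMap, electrode: str, window, regressor: str, component: str | None = None
) -> WindowScore:
    """Average a regressor's b-values over an inclusive ms window at one
    electrode (e.g. Pz 500–520 ms for the feedback P3b)."""
    ci = bmap.channel_index(electrode)
    ri = bmap.regressor_index(regressor)
    lo, hi = float(window[0]), float(window[1])
    mask = (bmap.times >= lo - 1e-9) & (bmap.times <= hi + 1e-9)
    if not mask.any():
        raise ParameterError(f"window [{lo}, {hi}] contains no samples")
    value = float(bmap.b[ci, mask, ri].mean())
    return WindowScore(bmap.subject, value, component or f"{electrode}:{lo}-{hi}ms")


# ---------------------------------------------------------------------------
# moderated regression across the grid
# ---------------------------------------------------------------------------

@dataclass
class ModerationFit:
    """Per-cell moderated-regression estimates.

    Arrays are (n_channels, n_times). ``cov11/cov12/cov22`` are the
    coefficient covariance entries for (β1, β2) needed by Johnson–Neyman;
    ``x_mean`` and ``m_mean`` are the centring means, so simple slopes can
    be reported in raw moderator units.
    """

    channels: list[str]
    times: np.ndarray
    b0: np.ndarray
    b1: np.ndarray
    b2: np.ndarray
    se1: np.ndarray
    se2: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    cov11: np.ndarray
    cov12: np.ndarray
    cov22: np.ndarray
    df: int
    moderator: str
    m_mean: float
    x_mean: float
    m_values: np.ndarray = field(repr=False, default=None)
    y_term: str | None = None
    x_component: str | None = None

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise DataError(f"channel {name!r} not in montage") from None

    def masked(self, p_mask: float, term: str = "interaction"):
        return mask_map(self, p_mask, term)

    def reported_df(self, convention: str = "model") -> int:
        """Degrees of freedom for reporting.

        ``model`` is the residual df used for inference (n − parameters);
        ``n_minus_1`` echoes the subject-count convention (n − 1) seen in
        some published tables, for comparison output only.
        """
        if convention == "model":
            return self.df
        if convention == "n_minus_1":
            return int(self.m_values.size - 1)
        raise ParameterError(f"convention must be model|n_minus_1, got {convention!r}")

    def johnson_neyman(self, electrode: str, time_ms: float, threshold: float = 0.01,
                       moderator_range=None) -> "JNResult":
        ci = self.channel_index(electrode)
        ti = int(np.argmin(np.abs(self.times - time_ms)))  # nearest sample
        if moderator_range is None:
            if self.m_values is None:
                raise ParameterError("moderator range required when m_values are absent")
            moderator_range = (float(np.min(self.m_values)), float(np.max(self.m_values)))
        return jn_points(
            b1=float(self.b1[ci, ti]),
            b2=float(self.b2[ci, ti]),
            cov11=float(self.cov11[ci, ti]),
            cov12=float(self.cov12[ci, ti]),
            cov22=float(self.cov22[ci, ti]),
            df=self.df,
            m_mean=self.m_mean,
            moderator_range=moderator_range,
            threshold=threshold,
            electrode=electrode,
            time_ms=float(self.times[ti]),
        )

    def peak(self, term: str = "interaction", p_mask: float | None = None):
        """(electrode, time, beta, t, p) of the maximal |t| cell for a term,
        optionally restricted to cells with p <= p_mask."""
        t = self.t2 if term == "interaction" else self.t1
        p = self.p2 if term == "interaction" else self.p1
        b = self.b2 if term == "interaction" else self.b1
        ok = np.ones(t.shape, bool) if p_mask is None else (p <= p_mask)
        if not ok.any():
            return None
        at = np.where(ok, np.abs(t), -np.inf)
        c, ti = np.unravel_index(np.argmax(at), at.shape)
        return {
            "electrode": self.channels[c],
            "time_ms": float(self.times[ti]),
            "beta": float(b[c, ti]),
            "t": float(t[c, ti]),
            "p": float(p[c, ti]),
            "df": self.df,
        }

    def summary(self) -> str:
        pk_main = self.peak("main")
        pk_int = self.peak("interaction")
        lines = [
            f"Moderated brain-brain regression: {self.y_term or 'first-level b'} ~ "
            f"{self.x_component or 'feedback effect'} x {self.moderator}",
            f"  cells: {len(self.channels)} channels x {self.times.size} time points, "
            f"residual df = {self.df}",
            f"  main-effect peak: {pk_main['electrode']} @ {pk_main['time_ms']:.0f} ms, "
            f"beta = {pk_main['beta']:.3f}, t = {pk_main['t']:.2f}, p = {pk_main['p']:.3g}",
            f"  interaction peak: {pk_int['electrode']} @ {pk_int['time_ms']:.0f} ms, "
            f"beta = {pk_int['beta']:.4f}, t = {pk_int['t']:.2f}, p = {pk_int['p']:.3g}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of all per-cell estimates."""
        c, t = np.meshgrid(np.arange(len(self.channels)), np.arange(self.times.size),
                           indexing="ij")
        return pd.DataFrame(
            {
                "electrode": np.asarray(self.channels)[c.ravel()],
                "time_ms": self.times[t.ravel()],
                "b0": self.b0.ravel(),
                "b1": self.b1.ravel(),
                "b2": self.b2.ravel(),
                "t1": self.t1.ravel(),
                "t2": self.t2.ravel(),
                "p1": self.p1.ravel(),
                "p2": self.p2.ravel(),
            }
        )


class ModeratedBrainRegression:
    """Model object: per-cell OLS of inhibition maps on a feedback score
    and its trait interaction.

    Parameters
    ----------
    y_maps : list of BetaMap
        One map per subject for the inhibition task (dependent variable).
    x : array-like or list of WindowScore
        Per-subject feedback-effect score.
    m : array-like
        Per-subject moderator (raw trait units).
    y_regressor : str
        Which regressor of the y maps to model (default 'trial_type').
    include_moderator_main : bool
        Add a centred moderator main-effect column (off by default; the
        two-predictor form is this package's reference model).
    """

    def __init__(self, y_maps, x, m, y_regressor="trial_type", moderator="moderator",
                 x_component=None, include_moderator_main=False):
        if len(y_maps) < 10:
            raise DataError(f"need at least 10 subjects, got {len(y_maps)}")
        if isinstance(x[0], WindowScore):
            x = [s.value for s in x]
        x = np.asarray(x, float)
        m = np.asarray(m, float)
        if not (len(y_maps) == x.size == m.size):
            raise DataError(
                f"subject counts differ: {len(y_maps)} maps, {x.size} scores, {m.size} moderators"
            )
        ref = y_maps[0]
        ri = ref.regressor_index(y_regressor)
        for mp in y_maps[1:]:
            if mp.channels != ref.channels or not np.allclose(mp.times, ref.times):
                raise DataError("subject grids differ across y maps")
        if np.ptp(x) == 0 or x.std() < 1e-12 * max(1.0, np.abs(x).mean()):
            raise DesignError("feedback score has (near-)zero variance")
        if np.ptp(m) == 0:
            raise DesignError("moderator is constant; interaction column is all zero")
        self.y = np.stack([mp.b[:, :, ri] for mp in y_maps])
        self.x = x
        self.m = m
        self.ref = ref
        self.y_regressor = y_regressor
        self.moderator = moderator
        self.x_component = x_component
        self.include_moderator_main = include_moderator_main

    def fit(self) -> ModerationFit:
        n = self.x.size
        x_c = self.x - self.x.mean()
        m_c = self.m - self.m.mean()
        cols = [np.ones(n), x_c, x_c * m_c]
        if self.include_moderator_main:
            cols.insert(2, m_c)
        X = np.column_stack(cols)
        p = X.shape[1]
        df = n - p
        if df < 1:
            raise DataError(f"not enough subjects ({n}) for {p} coefficients")
        xtx_inv = np.linalg.inv(X.T @ X)
        grid = self.y.shape[1:]
        Y = self.y.reshape(n, -1)
        B = xtx_inv @ X.T @ Y  # (p, cells)
        resid = Y - X @ B
        sigma2 = (resid**2).sum(axis=0) / df
        i1, i2 = 1, p - 1  # main effect, interaction (last column)
        se1 = np.sqrt(sigma2 * xtx_inv[i1, i1])
        se2 = np.sqrt(sigma2 * xtx_inv[i2, i2])
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(se1 > 0, B[i1] / se1, 0.0)
            t2 = np.where(se2 > 0, B[i2] / se2, 0.0)
        p1 = 2 * stats.t.sf(np.abs(t1), df)
        p2 = 2 * stats.t.sf(np.abs(t2), df)

        def g(a):
            return a.reshape(grid)

        return ModerationFit(
            channels=list(self.ref.channels),
            times=self.ref.times.copy(),
            b0=g(B[0]), b1=g(B[i1]), b2=g(B[i2]),
            se1=g(se1), se2=g(se2),
            t1=g(t1), t2=g(t2), p1=g(p1), p2=g(p2),
            cov11=g(sigma2 * xtx_inv[i1, i1]),
            cov12=g(sigma2 * xtx_inv[i1, i2]),
            cov22=g(sigma2 * xtx_inv[i2, i2]),
            df=df,
            moderator=self.moderator,
            m_mean=float(self.m.mean()),
            x_mean=float(self.x.mean()),
            m_values=self.m.copy(),
            y_term=self.y_regressor,
            x_component=self.x_component,
        )


def fit_moderated_map(y_maps, x, m, **kwargs) -> ModerationFit:
    """Per-cell OLS of y on [1, x_c, x_c·m_c] (demeaned product term)."""
    return ModeratedBrainRegression(y_maps, x, m, **kwargs).fit()


def mask_map(fit: ModerationFit, p_mask: float, term: str = "interaction"):
    """Suppress (NaN out) cells whose term p-value exceeds ``p_mask``.

    Uncorrected masking: no FDR is applied at the second level.
    """
    if not 0 < p_mask <= 1:
        raise ParameterError(f"p_mask must be in (0, 1], got {p_mask}")
    beta = fit.b2 if term == "interaction" else fit.b1
    p = fit.p2 if term == "interaction" else fit.p1
    keep = p <= p_mask
    return {
        "term": term,
        "beta": np.where(keep, beta, np.nan),
        "n_unmasked": int(keep.sum()),
        "p_mask": p_mask,
    }


# ---------------------------------------------------------------------------
# Johnson–Neyman regions of significance
# ---------------------------------------------------------------------------

@dataclass
class JNResult:
    """Johnson–Neyman boundaries and regions of significance at one cell.

    ``boundaries`` are in raw moderator units, clipped to the observed
    range; ``significant_intervals`` are the sub-intervals of the observed
    range where the simple slope's |t| exceeds the two-sided critical value.
    """

    electrode: str | None
    time_ms: float | None
    boundaries: list
    significant_intervals: list
    moderator_range: tuple
    threshold: float
    df: int

    def significant_at(self, m: float) -> bool:
        return any(lo - 1e-12 <= m <= hi + 1e-12 for lo, hi in self.significant_intervals)


def _slope_t(m_c, b1, b2, cov11, cov12, cov22):
    s = b1 + b2 * m_c
    var = cov11 + 2 * m_c * cov12 + m_c**2 * cov22
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(var > 0, s / np.sqrt(var), np.inf * np.sign(s))


def jn_points(
    b1: float,
    b2: float,
    cov11: float,
    cov12: float,
    cov22: float,
    df: int,
    m_mean: float = 0.0,
    moderator_range=(-np.inf, np.inf),
    threshold: float = 0.01,
    electrode: str | None = None,
    time_ms: float | None = None,
) -> JNResult:
    """Closed-form Johnson–Neyman boundaries for the simple slope.

    The simple slope s(m_c) = β1 + β2·m_c has SE²(m_c) = V11 + 2·m_c·V12 +
    m_c²·V22; boundaries are the real roots of s(m_c)² = t²_crit · SE²(m_c)
    (a quadratic in m_c) with t_crit the two-sided critical value at
    ``threshold`` and ``df``. Roots are reported in raw moderator units and
    clipped to the observed range; regions are labelled by evaluating the
    simple-slope |t| at interval midpoints.
    """
    if not 0 < threshold < 1:
        raise ParameterError(f"threshold must be in (0, 1), got {threshold}")
    lo, hi = float(moderator_range[0]), float(moderator_range[1])
    if not lo < hi:
        raise ParameterError(f"degenerate moderator range [{lo}, {hi}]")
    t_crit = stats.t.ppf(1 - threshold / 2, df)
    t2 = t_crit**2
    qa = b2**2 - t2 * cov22
    qb = 2 * (b1 * b2 - t2 * cov12)
    qc = b1**2 - t2 * cov11
    roots = []
    if abs(qa) > 1e-300:
        disc = qb**2 - 4 * qa * qc
        if disc >= 0:
            r = np.sqrt(disc)
            roots = [(-qb - r) / (2 * qa), (-qb + r) / (2 * qa)]
    elif abs(qb) > 1e-300:
        roots = [-qc / qb]
    raw = sorted(r + m_mean for r in roots)
    inside = [r for r in raw if lo < r < hi]

    edges = [lo] + inside + [hi]
    sig_intervals = []
    for a, b in zip(edges[:-1], edges[1:]):
        mid_c = (a + b) / 2 - m_mean
        if abs(_slope_t(mid_c, b1, b2, cov11, cov12, cov22)) > t_crit:
            if sig_intervals and sig_intervals[-1][1] == a:
                sig_intervals[-1] = (sig_intervals[-1][0], b)
            else:
                sig_intervals.append((a, b))
    return JNResult(
        electrode=electrode,
        time_ms=time_ms,
        boundaries=inside,
        significant_intervals=sig_intervals,
        moderator_range=(lo, hi),
        threshold=threshold,
        df=df,
    )


# ---------------------------------------------------------------------------
# residualised traits
# ---------------------------------------------------------------------------

def residualize(a, b) -> np.ndarray:
    """Raw residuals of the simple OLS of ``a`` on ``b`` (with intercept).

    Isolates the variance of one trait unique with respect to the other;
    the residuals have mean exactly 0 and are orthogonal to ``b``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size != b.size:
        raise DataError(f"trait vectors differ in length ({a.size} vs {b.size})")
    if np.ptp(b) == 0:
        raise DesignError("cannot residualise on a constant trait")
    b_c = b - b.mean()
    slope = (b_c @ (a - a.mean())) / (b_c @ b_c)
    resid = a - a.mean() - slope * b_c
    return resid - resid.mean()  # exact zero mean
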