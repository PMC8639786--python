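"""Structure-function statistics linking FC networks to tracer anatomy.

Anatomical projection strength is quantified by FLNe, the extrinsic fraction
of labeled neurons: after a retrograde injection in a target area, the share
of all extrinsically labeled neurons found in a given source area. The
laminar origin is quantified by SLN = Nsupra / (Nsupra + Ninfra); SLN > 0.5
marks feedforward, < 0.5 feedback projections. FLNe spans about five orders
of magnitude and decays exponentially with distance (the exponential
distance rule, EDR, with decay rate lambda per mm on a natural-log scale).

FC-anatomy coupling is measured by regressing log10(FC) on log10(FLNe); the
fitted FC ratio between the largest and smallest FLNe — the FLNe-related FC
fold change — is an effect-size metric that normalizes baseline FC
differences across frequencies. Multiple regression of log10(FLNe) on the
band-wise log10(FC) values plus distance disentangles anatomy from shared
distance decay; its R^2 is decomposed by commonality analysis (unique and
common variance over all predictor subsets, with negative commons flagging
suppressors), general dominance, and relative importance weights. Confidence
intervals come from a bootstrap over epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EDRFit",
    "RegressionResult",
    "MRResult",
    "ImportanceTable",
    "AsymmetryResult",
    "anatomy_metrics_from_counts",
    "symmetrize_anatomy",
    "filter_min_neurons",
    "edr_fit",
    "fc_flne_regression",
    "multiple_regression_flne",
    "predictor_importance",
    "sln_split_asymmetry",
    "gc_inflow_normalize",
    "bootstrap_over_epochs",
]


# ---------------------------------------------------------------------------
# anatomy tables

def anatomy_metrics_from_counts(counts_table: pd.DataFrame) -> pd.DataFrame:
    """Compute FLNe and SLN from a table of labeled-neuron counts.

    ``counts_table`` has one row per ordered (source, target) area pair with
    columns ``source, target, n_labeled, n_supra, n_infra`` (plus optional
    distance columns, carried through). Intrinsic (source == target) rows are
    excluded from the extrinsic denominator and dropped. FLNe of source s for
    target t is ``n_labeled(s, t) / sum_s' n_labeled(s', t)``, so FLNe sums
    to 1 over the extrinsic sources of each target.
    """
    df = counts_table.copy()
    for col in ("n_labeled", "n_supra", "n_infra"):
        if col in df and (np.asarray(df[col]) < 0).any():
            raise ValueError(f"negative counts in column {col}")
    df = df[df["source"] != df["target"]].copy()
    totals = df.groupby("target")["n_labeled"].transform("sum")
    if (totals <= 0).any():
        bad = df.loc[totals <= 0, "target"].unique()
        raise ValueError(f"zero total extrinsic count for target(s) {list(bad)}")
    df["flne"] = df["n_labeled"] / totals
    denom = df["n_supra"] + df["n_infra"]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["sln"] = np.where(denom > 0, df["n_supra"] / denom, np.nan)
    return df.reset_index(drop=True)


def symmetrize_anatomy(anatomy: pd.DataFrame) -> pd.DataFrame:
    """Undirected anatomy table: average FLNe over the two directions per pair.

    Counts are combined (summed) so the minimum-neuron filter can act on the
    joint count; distances are averaged.
    """
    df = anatomy.copy()
    key = [tuple(sorted((s, t))) for s, t in zip(df["source"], df["target"])]
    df["_pair"] = key
    agg = {"flne": "mean", "n_labeled": "sum"}
    for col in ("dist_wm_mm", "dist_surface_mm"):
        if col in df:
            agg[col] = "mean"
    out = df.groupby("_pair").agg(agg).reset_index()
    out[["area_a", "area_b"]] = pd.DataFrame(out["_pair"].tolist(), index=out.index)
    return out.drop(columns="_pair")


def filter_min_neurons(anatomy: pd.DataFrame, min_count: int = 10) -> pd.DataFrame:
    """Drop projections whose FLNe rests on fewer than ``min_count`` labeled neurons.

    The boundary is exclusive (entries with exactly ``min_count`` neurons are
    retained). For symmetrized tables the combined two-direction count is
    what is thresholded.
    """
    return anatomy[anatomy["n_labeled"] >= min_count].reset_index(drop=True)


# ---------------------------------------------------------------------------
# regressions

@dataclass
class EDRFit:
    """Exponential-distance-rule fit: ln(weight) = -lambda * d + intercept."""

    lam: float
    intercept: float
    r2: float
    n: int
    log_base: str = "natural"


def edr_fit(weights: np.ndarray, distances: np.ndarray) -> EDRFit:
    """Least-squares fit of ln(weight) on distance; lambda = -slope (1/mm)."""
    w = np.asarray(weights, float)
    d = np.asarray(distances, float)
    if w.shape != d.shape:
        raise ValueError("weights and distances must align")
    if np.any(w <= 0):
        raise ValueError(
            f"non-positive weights at indices {np.flatnonzero(w <= 0).tolist()}"
        )
    if w.size < 3:
        raise ValueError("need >= 3 points")
    res = stats.linregress(d, np.log(w))
    return EDRFit(lam=-float(res.slope), intercept=float(res.intercept),
                  r2=float(res.rvalue**2), n=int(w.size))


@dataclass
class RegressionResult:
    """log10-log10 regression of FC on FLNe with fold-change effect size."""

    slope: float
    intercept: float
    r2: float
    p: float
    n: int
    bonferroni_m: int
    fold_change: float
    significant: bool
    ci_999: Optional[Tuple[float, float]] = None  # bootstrap CI of fold change


def _loglog_fit(fc: np.ndarray, flne: np.ndarray, bonferroni_m: int) -> RegressionResult:
    keep = np.isfinite(fc) & np.isfinite(flne) & (fc > 0) & (flne > 0)
    x = np.log10(flne[keep])
    y = np.log10(fc[keep])
    if x.size < 3:
        raise ValueError(f"only {x.size} usable pairs; need >= 3")
    res = stats.linregress(x, y)
    span = x.max() - x.min()
    fold = 10.0 ** (res.slope * span)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue**2), p=float(res.pvalue), n=int(x.size),
        bonferroni_m=bonferroni_m, fold_change=float(fold),
        significant=bool(res.pvalue < 0.05 / bonferroni_m),
    )


def fc_flne_regression(
    fc_values: np.ndarray,
    flne_values: np.ndarray,
    per_frequency: bool = False,
    bonferroni_m: int = 12,
    n_boot: int = 100,
    ci_level: float = 0.999,
    seed: int = 0,
    fc_resampler: Optional[Callable[[np.random.Generator], np.ndarray]] = None,
) -> Union[RegressionResult, List[RegressionResult]]:
    """Linear regression between log10(FC) and log10(FLNe).

    Returns slope, R^2, p (declared significant at 0.05 / ``bonferroni_m``),
    and the FLNe-related fold change: the ratio of fitted FC at the maximum
    vs minimum observed log10(FLNe), i.e. ``10^(slope * range)``. Zero or
    non-finite values are excluded (counts reflected in ``n``).

    With ``per_frequency`` the FC array is (n_obs, n_freq) and one result per
    frequency bin is returned. If ``fc_resampler`` is given (a callable
    mapping an RNG to a bootstrap replicate of the FC values, e.g. FC
    recomputed from epochs resampled with replacement), ``n_boot`` replicates
    yield a percentile confidence interval for the fold change at
    ``ci_level``.
    """
    fc_values = np.asarray(fc_values, float)
    flne = np.asarray(flne_values, float)
    if per_frequency:
        results = [
            _loglog_fit(fc_values[:, k], flne, bonferroni_m)
            for k in range(fc_values.shape[1])
        ]
    else:
        results = _loglog_fit(fc_values, flne, bonferroni_m)
    if fc_resampler is None:
        return results
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        fc_b = np.asarray(fc_resampler(rng), float)
        if per_frequency:
            boots.append([
                _loglog_fit(fc_b[:, k], flne, bonferroni_m).fold_change
                for k in range(fc_b.shape[1])
            ])
        else:
            boots.append(_loglog_fit(fc_b, flne, bonferroni_m).fold_change)
    boots = np.asarray(boots)
    lo_q, hi_q = 100 * (1 - ci_level) / 2, 100 * (1 + ci_level) / 2
    if per_frequency:
        for k, r in enumerate(results):
            r.ci_999 = (float(np.percentile(boots[:, k], lo_q)),
                        float(np.percentile(boots[:, k], hi_q)))
    else:
        results.ci_999 = (float(np.percentile(boots, lo_q)),
                          float(np.percentile(boots, hi_q)))
    return results


@dataclass
class MRResult:
    """Multiple regression of log10(FLNe) on band-wise log10(FC) and distance."""

    predictor_names: List[str]
    coefficients: np.ndarray  # raw OLS coefficients (no intercept entry)
    beta_std: np.ndarray  # standardized coefficients
    intercept: float
    t_stats: np.ndarray
    p_values: np.ndarray
    r2_full: float
    delta_r2: Dict[str, float]  # R2(full) - R2(without predictor)
    vif: Dict[str, float]
    n: int


def _ols_r2(X: np.ndarray, y: np.ndarray) -> float:
    """R^2 of an OLS fit with intercept."""
    if X.shape[1] == 0:
        return 0.0
    A = np.column_stack([np.ones(len(y)), X])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    return float(1.0 - np.sum(resid**2) / ss_tot)


def multiple_regression_flne(
    flne: np.ndarray,
    fc_by_band: Union[Dict[str, np.ndarray], np.ndarray],
    distance: Optional[np.ndarray] = None,
    band_names: Optional[Sequence[str]] = None,
    log_fc: bool = True,
) -> MRResult:
    """OLS of log10(FLNe) on band-wise log10(FC) and (non-log) distance.

    Only complete cases (finite, positive where logs are taken) enter. VIFs
    come from auxiliary regressions of each predictor on the others;
    ``delta_r2`` is the loss in R^2 when refitting without that predictor
    (stepwise-style contribution). Perfect collinearity raises an error
    naming the dependent column.
    """
    import statsmodels.api as sm

    if isinstance(fc_by_band, dict):
        names = list(fc_by_band.keys())
        Xfc = np.column_stack([np.asarray(fc_by_band[b], float) for b in names])
    else:
        Xfc = np.asarray(fc_by_band, float)
        if Xfc.ndim == 1:
            Xfc = Xfc[:, None]
        names = list(band_names) if band_names is not None else [
            f"fc{k + 1}" for k in range(Xfc.shape[1])
        ]
    flne = np.asarray(flne, float)
    keep = np.isfinite(flne) & (flne > 0) & np.all(np.isfinite(Xfc), axis=1)
    if log_fc:
        keep &= np.all(Xfc > 0, axis=1)
    cols = [np.log10(Xfc[keep]) if log_fc else Xfc[keep]]
    if distance is not None:
        d = np.asarray(distance, float)
        keep_d = np.isfinite(d)
        # recompute keep including distance finiteness
        keep = keep & keep_d
        cols = [np.log10(Xfc[keep]) if log_fc else Xfc[keep], d[keep][:, None]]
        names = names + ["distance"]
    X = np.column_stack(cols)
    y = np.log10(flne[keep])
    p = X.shape[1]
    if len(y) < p + 3:
        raise ValueError(f"need >= {p + 3} complete cases, have {len(y)}")
    # collinearity guard: auxiliary R2 of each predictor on the rest
    vif = {}
    for k, nm in enumerate(names):
        others = np.delete(X, k, axis=1)
        r2_aux = _ols_r2(others, X[:, k]) if p > 1 else 0.0
        if r2_aux > 1 - 1e-12:
            raise ValueError(f"perfect collinearity: predictor {nm!r} is a linear "
                             "combination of the others")
        vif[nm] = float(1.0 / (1.0 - r2_aux))
    model = sm.OLS(y, sm.add_constant(X)).fit()
    r2_full = float(model.rsquared)
    delta = {}
    for k, nm in enumerate(names):
        delta[nm] = r2_full - _ols_r2(np.delete(X, k, axis=1), y)
    sx = X.std(axis=0, ddof=1)
    sy = y.std(ddof=1)
    return MRResult(
        predictor_names=names,
        coefficients=np.asarray(model.params[1:]),
        beta_std=np.asarray(model.params[1:]) * sx / sy,
        intercept=float(model.params[0]),
        t_stats=np.asarray(model.tvalues[1:]),
        p_values=np.asarray(model.pvalues[1:]),
        r2_full=r2_full,
        delta_r2=delta,
        vif=vif,
        n=int(len(y)),
    )


@dataclass
class ImportanceTable:
    """Variance decompositions of a multiple regression's R^2.

    ``table`` has one row per predictor with columns ``unique`` (direct
    effect), ``common`` (summed shared effects involving the predictor; may
    be negative, flagging suppression), ``rs2`` (squared structure
    coefficient), ``gendom`` (general dominance weight), and ``riw``
    (relative importance weight). ``commonalities`` maps each predictor
    subset to its commonality coefficient; unique plus all subset commons
    (each counted once) sum to ``r2_full``, as do the gendom and riw columns.
    """

    table: pd.DataFrame
    r2_full: float
    commonalities: Dict[frozenset, float]


def predictor_importance(
    y: np.ndarray,
    predictors: Union[pd.DataFrame, np.ndarray],
    names: Optional[Sequence[str]] = None,
    max_predictors: int = 12,
) -> ImportanceTable:
    """Commonality, general dominance, and relative-weights decomposition of R^2.

    All-possible-subsets R^2 values feed three decompositions: (1)
    commonality analysis via Moebius inversion of the subset lattice, giving
    the unique effect of each predictor and the common effect of every
    predictor subset (negative commons identify suppressor variables); (2)
    general dominance, the mean conditional R^2 contribution of a predictor
    over all subset sizes; (3) relative importance weights via the
    orthogonal-approximation (SVD) method. Squared structure coefficients
    rs^2 = r(x_i, y_hat)^2 are reported alongside. The gendom and riw columns
    and the full commonality decomposition each sum to the full-model R^2.
    """
    if isinstance(predictors, pd.DataFrame):
        names = list(predictors.columns)
        X = predictors.to_numpy(dtype=float)
    else:
        X = np.asarray(predictors, float)
        if names is None:
            names = [f"x{k + 1}" for k in range(X.shape[1])]
        names = list(names)
    y = np.asarray(y, float)
    p = X.shape[1]
    if p > max_predictors:
        raise ValueError(
            f"{p} predictors exceed the all-subsets limit of {max_predictors}"
        )
    if len(y) < p + 3:
        raise ValueError("too few observations")

    full = frozenset(range(p))
    r2 = {frozenset(): 0.0}
    for k in range(1, p + 1):
        for sub in combinations(range(p), k):
            s = frozenset(sub)
            r2[s] = _ols_r2(X[:, sorted(s)], y)
    r2_full = r2[full]

    # commonality: C(S) = sum_{T subseteq S} (-1)^{|S|-|T|} g(T),
    # g(T) = R2(full) - R2(full \ T)
    def g(T: frozenset) -> float:
        return r2_full - r2[full - T]

    commonalities = {}
    for k in range(1, p + 1):
        for sub in combinations(range(p), k):
            S = frozenset(sub)
            c = 0.0
            for m in range(0, k + 1):
                for tsub in combinations(sorted(S), m):
                    c += (-1) ** (k - m) * g(frozenset(tsub))
            commonalities[S] = c
    unique = np.array([commonalities[frozenset([i])] for i in range(p)])
    common = np.array([
        sum(c for S, c in commonalities.items() if i in S and len(S) >= 2)
        for i in range(p)
    ])

    # general dominance
    gendom = np.zeros(p)
    for i in range(p):
        contribs_by_size = []
        for k in range(0, p):
            vals = [
                r2[frozenset(T) | {i}] - r2[frozenset(T)]
                for T in combinations(sorted(full - {i}), k)
            ]
            contribs_by_size.append(np.mean(vals))
        gendom[i] = np.mean(contribs_by_size)

    # relative importance weights (orthogonal approximation)
    Xs = (X - X.mean(0)) / X.std(0, ddof=1) / np.sqrt(len(y) - 1)
    ys = (y - y.mean()) / y.std(ddof=1) / np.sqrt(len(y) - 1)
    U, s_, Vt = np.linalg.svd(Xs, full_matrices=False)
    Z = U @ Vt
    Lam = Vt.T @ np.diag(s_) @ Vt
    beta = Z.T @ ys
    riw = (Lam**2) @ (beta**2)

    # squared structure coefficients
    A = np.column_stack([np.ones(len(y)), X])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    yhat = A @ coef
    rs2 = np.array([
        np.corrcoef(X[:, i], yhat)[0, 1] ** 2 if np.std(yhat) > 0 else np.nan
        for i in range(p)
    ])

    table = pd.DataFrame(
        {"unique": unique, "common": common, "rs2": rs2,
         "gendom": gendom, "riw": riw},
        index=pd.Index(names, name="predictor"),
    )
    return ImportanceTable(table=table, r2_full=r2_full,
                           commonalities=commonalities)


# ---------------------------------------------------------------------------
# SLN split, GC normalization, bootstrap

@dataclass
class AsymmetryResult:
    """Feedforward/feedback split of the FLNe-related GC change.

    ``asymmetry_index`` = (feedforward - feedback) / (feedforward + feedback)
    applied elementwise to the two fold-change spectra; bounded in [-1, 1]
    whenever both spectra are positive.
    """

    freqs: Optional[np.ndarray]
    ff_change_spectrum: np.ndarray
    fb_change_spectrum: np.ndarray
    asymmetry_index: np.ndarray
    sln_threshold: Tuple[float, float]
    ff_n: int
    fb_n: int
    threshold_sweep: Optional[Dict[float, dict]] = None


def _fold_spectrum(gc: np.ndarray, flne: np.ndarray, bonferroni_m: int) -> np.ndarray:
    if gc.ndim == 1:
        gc = gc[:, None]
    out = np.full(gc.shape[1], np.nan)
    for k in range(gc.shape[1]):
        try:
            out[k] = _loglog_fit(gc[:, k], flne, bonferroni_m).fold_change
        except ValueError:
            pass
    return out


def sln_split_asymmetry(
    gc_values: np.ndarray,
    flne: np.ndarray,
    sln: np.ndarray,
    ff_cut: float = 0.7,
    fb_cut: float = 0.3,
    threshold_grid: Optional[Sequence[Tuple[float, float]]] = None,
    freqs: Optional[np.ndarray] = None,
    bonferroni_m: int = 12,
) -> AsymmetryResult:
    """FLNe-related GC change split by feedforward vs feedback projections.

    Projections with SLN > ``ff_cut`` form the strongly feedforward group and
    SLN < ``fb_cut`` the strongly feedback group; GC must be matched to the
    same-direction FLNe. Each group's fold-change spectrum comes from the
    log-log FC~FLNe regression per frequency; the asymmetry index is their
    normalized difference. Groups with fewer than 3 projections are skipped
    (NaN spectrum, logged). ``threshold_grid`` optionally sweeps alternative
    (ff_cut, fb_cut) pairs.
    """
    gc_values = np.asarray(gc_values, float)
    flne = np.asarray(flne, float)
    sln = np.asarray(sln, float)

    def group_spec(mask: np.ndarray) -> np.ndarray:
        nf = gc_values.shape[1] if gc_values.ndim == 2 else 1
        if mask.sum() < 3:
            logger.warning("SLN group with %d projections skipped", int(mask.sum()))
            return np.full(nf, np.nan)
        return _fold_spectrum(gc_values[mask], flne[mask], bonferroni_m)

    ff_mask = sln > ff_cut
    fb_mask = sln < fb_cut
    ff = group_spec(ff_mask)
    fb = group_spec(fb_mask)
    with np.errstate(divide="ignore", invalid="ignore"):
        asym = (ff - fb) / (ff + fb)
    sweep = None
    if threshold_grid is not None:
        sweep = {}
        for (fc_, bc_) in threshold_grid:
            f_ = group_spec(sln > fc_)
            b_ = group_spec(sln < bc_)
            with np.errstate(divide="ignore", invalid="ignore"):
                sweep[(fc_, bc_)] = {
                    "ff": f_, "fb": b_, "asymmetry": (f_ - b_) / (f_ + b_),
                }
    return AsymmetryResult(
        freqs=freqs, ff_change_spectrum=ff, fb_change_spectrum=fb,
        asymmetry_index=asym, sln_threshold=(ff_cut, fb_cut),
        ff_n=int(ff_mask.sum()), fb_n=int(fb_mask.sum()),
        threshold_sweep=sweep,
    )


def gc_inflow_normalize(gc_band_matrix: np.ndarray) -> np.ndarray:
    """Normalize GC from A to B by the total GC inflow to B from all sources.

    Each entry is divided by its column (target) sum over sources (diagonal
    excluded); columns with zero total inflow are flagged NaN. Every column
    of the result sums to 1.
    """
    W = np.asarray(gc_band_matrix, float).copy()
    n = W.shape[0]
    np.fill_diagonal(W, 0.0)
    colsum = np.nansum(W, axis=0)
    out = np.full_like(W, np.nan)
    for j in range(n):
        if colsum[j] > 0:
            out[:, j] = W[:, j] / colsum[j]
    np.fill_diagonal(out, np.nan)
    return out


def bootstrap_over_epochs(
    statistic_fn: Callable[[np.ndarray], Union[float, np.ndarray]],
    n_epochs: int,
    n_boot: int = 100,
    ci_level: float = 0.999,
    seed: int = 0,
    max_redraws: int = 1000,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Percentile bootstrap over epochs for an arbitrary statistic.

    ``statistic_fn`` receives an integer array of epoch indices (resampled
    with replacement) and must return the statistic for that resample.
    Resamples on which the statistic is undefined (NaN) are redrawn (the
    count is logged). Returns ``(lo, hi, estimates)`` with the percentile
    interval at ``ci_level``.
    """
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50")
    rng = np.random.default_rng(seed)
    estimates = []
    redraws = 0
    while len(estimates) < n_boot:
        idx = rng.integers(0, n_epochs, size=n_epochs)
        val = np.asarray(statistic_fn(idx), float)
        if np.isnan(val).any():
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("statistic undefined on too many resamples")
            continue
        estimates.append(val)
    if redraws:
        logger.info("bootstrap_over_epochs: redrew %d undefined resamples", redraws)
    estimates = np.asarray(estimates)
    lo_q, hi_q = 100 * (1 - ci_level) / 2, 100 * (1 + ci_level) / 2
    lo = np.percentile(estimates, lo_q, axis=0)
    hi = np.percentile(estimates, hi_q, axis=0)
    return lo, hi, estimates
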