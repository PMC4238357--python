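"""Differential expression for two-color dye-swap arrays.

Pipeline, in order:

1. **Net intensity** -- foreground minus local background per channel,
   floored at a small epsilon (0.5) before logging.
2. **PM>MM filter** (on raw net intensities) -- a candidate is considered
   for differential expression only if its mean PM net intensity strictly
   exceeds its mean MM net intensity under at least one experimental
   condition; probes without an MM partner pass automatically and are
   flagged.
3. **M/A computation** -- per spot, M = log2 ratio oriented case-minus-
   control (fixed orientation regardless of which dye carries which
   condition), A = mean log2 intensity of the two channels.
4. **Within-array normalization** -- robust local linear regression
   (lowess, span 0.4, 4 robustness iterations) of M on A per print-tip
   group; M is replaced by its residual, A is untouched.  Blocks with
   fewer than 20 spots fall back to a whole-array fit.
5. **Between-array normalization** -- quantile normalization of the
   A-values across arrays (sorted A vectors become identical); M is
   preserved so within-array contrasts are not disturbed.
6. **Dye-swap linear model** -- per candidate, replicate spots are combined
   per array (mean by default, or GLS under a common replicate-spot
   correlation), and the per-array values give the fold-change estimate
   beta_hat with residual variance s_g^2 on d_g degrees of freedom.
7. **Empirical-Bayes moderation** -- the gene-wise variances are shrunk
   toward a chip-wide prior s0^2 with d0 prior degrees of freedom fitted by
   moment matching on log s_g^2 (digamma/trigamma equations); the
   moderated t-statistic is referred to a t distribution with d0 + d_g df
   (normal when d0 is infinite).
8. **BH adjustment** -- Benjamini-Hochberg step-up; candidates with
   adjusted p < 0.05 are called differentially expressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess
from statsmodels.stats.multitest import multipletests

from .hyb_simulator import TwoColorScan

__all__ = [
    "MAMatrix",
    "ModerationFit",
    "net_intensity",
    "make_ma",
    "normalize_within",
    "normalize_between",
    "pm_mm_filter",
    "fit_dyeswap",
    "ebayes",
    "bh_adjust",
    "run_de_analysis",
]

NET_FLOOR = 0.5


@dataclass
class MAMatrix:
    """Per-spot M (case-minus-control log2 ratio) and A values for one array."""

    array_id: str
    spots: pd.DataFrame  # columns: Name, pair_role, Block, Row, Column, M, A


@dataclass
class ModerationFit:
    """Empirical-Bayes variance prior: d0 (may be inf) and s0^2."""

    d0: float
    s0_sq: float


def net_intensity(scan: TwoColorScan, floor: float = NET_FLOOR) -> pd.DataFrame:
    """Foreground minus local background per channel, floored at ``floor``."""
    net635 = (scan.spots["F635 Median"] - scan.spots["B635 Median"]).clip(lower=floor)
    net532 = (scan.spots["F532 Median"] - scan.spots["B532 Median"]).clip(lower=floor)
    out = scan.spots[["Block", "Row", "Column", "ID", "Name"]].copy()
    if "pair_role" not in out.columns:
        out["pair_role"] = _roles_from_ids(scan.spots["ID"])
    out["net635"], out["net532"] = net635, net532
    return out


def _roles_from_ids(ids: pd.Series) -> pd.Series:
    def role(spot_id: str) -> str:
        parts = str(spot_id).rsplit(".", 2)
        return parts[1] if len(parts) == 3 and parts[1] in ("PM", "MM") else "single"

    return ids.map(role)


def make_ma(
    scan: TwoColorScan,
    case: str = "case",
    control: str = "control",
    floor: float = NET_FLOOR,
) -> MAMatrix:
    """M/A values with M oriented case-minus-control using the scan's dye map."""
    net = net_intensity(scan, floor)
    log635, log532 = np.log2(net["net635"]), np.log2(net["net532"])
    if scan.dye_assignment["ch635"] == case:
        m = log635 - log532
    elif scan.dye_assignment["ch532"] == case:
        m = log532 - log635
    else:
        raise ValueError(
            f"array {scan.array_id}: no channel assigned to condition {case!r}"
        )
    if scan.dye_assignment["ch635"] == scan.dye_assignment["ch532"]:
        raise ValueError(f"array {scan.array_id}: both channels assigned the same condition")
    spots = net[["Block", "Row", "Column", "Name", "pair_role"]].copy()
    spots["M"] = m
    spots["A"] = (log635 + log532) / 2.0
    return MAMatrix(scan.array_id, spots)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_within(
    ma: MAMatrix,
    min_spots_per_block: int = 20,
    frac: float = 0.4,
    iterations: int = 4,
) -> MAMatrix:
    """Print-tip loess: per block, residualize M against a robust local
    linear regression on A.  A is untouched.  Blocks with fewer than
    ``min_spots_per_block`` spots fall back to a single whole-array fit.
    """
    spots = ma.spots.copy()
    m = spots["M"].to_numpy(dtype=float)
    a = spots["A"].to_numpy(dtype=float)
    blocks = spots["Block"].to_numpy()

    small = {b for b, n in zip(*np.unique(blocks, return_counts=True)) if n < min_spots_per_block}
    fallback = np.isin(blocks, list(small)) if small else np.zeros(len(blocks), bool)

    new_m = m.copy()

    def _residualize(mask: np.ndarray) -> np.ndarray:
        aa, mm = a[mask], m[mask]
        span = float(aa.max() - aa.min())
        fit = _lowess(mm, aa, frac=frac, it=iterations, delta=0.01 * span, return_sorted=False)
        return mm - fit

    if fallback.any():
        # small blocks share a single whole-array fit
        whole = _residualize(np.ones(len(blocks), dtype=bool))
        new_m[fallback] = whole[fallback]
    for b in np.unique(blocks):
        if b not in small:
            mask = blocks == b
            new_m[mask] = _residualize(mask)
    spots["M"] = new_m
    return MAMatrix(ma.array_id, spots)


def normalize_between(ma_list: Sequence[MAMatrix]) -> list[MAMatrix]:
    """Quantile-normalize A across arrays; M is preserved.

    After the call the sorted A vectors of all arrays are identical (the
    rank-wise mean of the input distributions).  Idempotent.
    """
    if len(ma_list) < 2:
        raise ValueError("quantile normalization needs at least 2 arrays")
    n = len(ma_list[0].spots)
    for ma in ma_list:
        if len(ma.spots) != n:
            raise ValueError(
                f"arrays differ in spot count ({len(ma.spots)} vs {n}); "
                "quantile normalization requires identical layouts"
            )
    a_mat = np.column_stack([ma.spots["A"].to_numpy(dtype=float) for ma in ma_list])
    reference = np.sort(a_mat, axis=0).mean(axis=1)
    out = []
    for j, ma in enumerate(ma_list):
        order = np.argsort(a_mat[:, j], kind="stable")
        new_a = np.empty(n)
        new_a[order] = reference
        spots = ma.spots.copy()
        spots["A"] = new_a
        out.append(MAMatrix(ma.array_id, spots))
    return out


# ---------------------------------------------------------------------------
# PM > MM filter
# ---------------------------------------------------------------------------

def pm_mm_filter(
    scans: Sequence[TwoColorScan],
    sheet: pd.DataFrame,
    conditions: tuple[str, str] = ("case", "control"),
    floor: float = NET_FLOOR,
) -> pd.DataFrame:
    """Specificity filter on raw net intensities.

    For each candidate and each condition, the condition-level PM (and MM)
    intensity is the mean net intensity over every spot, array and channel
    assigned to that condition.  A candidate passes when PM strictly
    exceeds MM in at least one condition.  Candidates without MM spots
    (control-region, spike-in, snRNA probes) pass automatically and are
    flagged via ``has_mm = False``.

    Returns a DataFrame indexed by candidate with columns ``has_mm`` and
    ``passed``.
    """
    dye_of = {row.array_id: (row.ch635_condition, row.ch532_condition) for row in sheet.itertuples()}
    frames = []
    for scan in scans:
        net = net_intensity(scan, floor)
        cond635, cond532 = dye_of[scan.array_id]
        for channel, cond in (("net635", cond635), ("net532", cond532)):
            frames.append(
                pd.DataFrame(
                    {
                        "Name": net["Name"],
                        "pair_role": net["pair_role"],
                        "condition": cond,
                        "net": net[channel],
                    }
                )
            )
    long = pd.concat(frames, ignore_index=True)
    means = (
        long.groupby(["Name", "pair_role", "condition"], sort=False)["net"].mean().unstack("pair_role")
    )
    out_rows = {}
    for name, sub in means.groupby(level="Name", sort=False):
        has_mm = "MM" in sub.columns and sub["MM"].notna().any()
        if has_mm:
            passed = bool((sub["PM"] > sub["MM"]).any())
        else:
            passed = True
        out_rows[name] = {"has_mm": has_mm, "passed": passed}
    out = pd.DataFrame.from_dict(out_rows, orient="index")
    out.index.name = "candidate_id"
    return out


# ---------------------------------------------------------------------------
# Dye-swap linear model
# ---------------------------------------------------------------------------

def _estimate_dup_correlation(values: pd.DataFrame) -> float:
    """Common correlation of replicate spots within arrays.

    ``values``: long frame with columns Name, array_id, M.  Moment
    estimator: the within-(gene, array) spot variance estimates
    sigma^2 (1 - rho); the across-array variance of per-array means
    estimates sigma^2 (1 + (m-1) rho)/m plus the array-to-array component,
    so rho is solved from the pooled within/total decomposition.
    """
    grp = values.groupby(["Name", "array_id"], sort=False)["M"]
    within = grp.var(ddof=1).dropna()
    m = grp.size().median()
    total = values.groupby("Name", sort=False)["M"].var(ddof=1).dropna()
    w, t = float(within.median()), float(total.median())
    if t <= 0 or w <= 0:
        return 0.0
    rho = 1.0 - w / t
    return float(np.clip(rho, 0.0, 0.99))


def fit_dyeswap(
    ma_list: Sequence[MAMatrix],
    sheet: pd.DataFrame | None = None,
    dup_method: Literal["average", "gls"] = "average",
) -> pd.DataFrame:
    """Per-candidate fold-change estimate from sign-aligned M values.

    M values are already case-minus-control oriented by :func:`make_ma`, so
    the model per candidate is simply ``M = beta + error`` across arrays.
    Replicate spots within an array are combined by ``dup_method``:

    ``"average"`` (default)
        per-array spot mean; ``beta_hat`` is the mean of the per-array
        values, ``s2`` their sample variance, ``df = n_arrays - 1``.
    ``"gls"``
        generalized least squares on all spot-level values under a common
        replicate-spot correlation rho (estimated chip-wide by moments).
        With balanced replication the point estimate equals the spot mean;
        the residual variance and degrees of freedom use all spots.

    MM spots never enter the fit.  Returns a DataFrame indexed by candidate
    with columns beta, s2, df, n_arrays, v (unscaled variance of beta).
    """
    if len(ma_list) < 2:
        raise ValueError("dye-swap fit needs at least 2 arrays")
    frames = []
    for ma in ma_list:
        sub = ma.spots.loc[ma.spots["pair_role"] != "MM", ["Name", "M"]].copy()
        sub["array_id"] = ma.array_id
        frames.append(sub)
    long = pd.concat(frames, ignore_index=True)

    grp = long.groupby(["Name", "array_id"], sort=False)["M"]
    per_array = grp.mean().unstack("array_id")
    n_arrays = per_array.notna().sum(axis=1)

    if dup_method == "average":
        beta = per_array.mean(axis=1)
        s2 = per_array.var(axis=1, ddof=1)
        df = (n_arrays - 1).astype(float)
        v = 1.0 / n_arrays
    elif dup_method == "gls":
        rho = _estimate_dup_correlation(long)
        m = grp.size().unstack("array_id")  # spots per gene per array
        # GLS weight of an array mean under equicorrelated replicate spots
        weight = m / (1.0 + (m - 1.0) * rho)
        beta = (per_array * weight).sum(axis=1) / weight.sum(axis=1)
        # Mahalanobis residual: within-array spot scatter + weighted scatter
        # of the array means around beta
        within_ss = (
            ((long.set_index(["Name", "array_id"])["M"] - grp.mean()) ** 2)
            .groupby(level="Name")
            .sum()
        )
        q = within_ss / (1.0 - rho) + (
            (per_array.sub(beta, axis=0) ** 2) * weight
        ).sum(axis=1)
        n_spots_total = m.sum(axis=1)
        df = (n_spots_total - 1).astype(float)
        s2 = q / df
        v = 1.0 / weight.sum(axis=1)
    else:
        raise ValueError(f"unknown dup_method {dup_method!r}")

    out = pd.DataFrame(
        {"beta": beta, "s2": s2, "df": df.astype(float), "n_arrays": n_arrays, "v": v}
    )
    out.index.name = "candidate_id"
    return out


# ---------------------------------------------------------------------------
# Empirical Bayes moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def ebayes(fit: pd.DataFrame, min_candidates: int = 10) -> tuple[ModerationFit, pd.DataFrame]:
    """Moderated t-statistics with a chip-wide variance prior.

    The prior (d0, s0^2) is fitted by moment matching on log s_g^2: with
    e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2), the mean of e_g
    identifies s0^2 and the excess variance of e_g over trigamma(d_g/2)
    identifies trigamma(d0/2).  When the observed variances show no excess
    dispersion the moment equation gives d0 = +inf: every gene then uses
    s0^2 and the statistic is referred to the normal distribution.

    Returns the :class:`ModerationFit` and a copy of ``fit`` with columns
    s2_post, t, p added.
    """
    usable = fit[(fit["df"] > 0) & (fit["s2"] > 0)]
    if len(usable) < min_candidates:
        raise ValueError(
            f"only {len(usable)} candidates with positive residual df; "
            "too few to fit the variance prior -- use an exact t-test instead"
        )
    d = usable["df"].to_numpy(dtype=float)
    z = np.log(usable["s2"].to_numpy(dtype=float))
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(e.mean())
    n = len(e)
    excess = float(np.mean((e - e_mean) ** 2 * n / (n - 1) - special.polygamma(1, d / 2.0)))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = math.inf
        s0_sq = float(np.exp(e_mean))
    prior = ModerationFit(d0=d0, s0_sq=s0_sq)

    out = fit.copy()
    d_all = out["df"].to_numpy(dtype=float)
    s2_all = out["s2"].to_numpy(dtype=float)
    if math.isinf(d0):
        s2_post = np.full_like(s2_all, s0_sq)
    else:
        s2_post = (d0 * s0_sq + d_all * s2_all) / (d0 + d_all)
    t = out["beta"].to_numpy(dtype=float) / np.sqrt(s2_post * out["v"].to_numpy(dtype=float))
    if math.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=d0 + d_all)
    out["s2_post"], out["t"], out["p"] = s2_post, t, p
    return prior, out


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_de_analysis(
    scans: Sequence[TwoColorScan],
    sheet: pd.DataFrame,
    conditions: tuple[str, str] = ("case", "control"),
    dup_method: Literal["average", "gls"] = "average",
    alpha: float = 0.05,
    biotypes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Scans -> DE table: the full statistics pipeline in one call.

    The PM>MM filter runs on raw net intensities; candidates failing it are
    reported with NaN statistics and ``de_call = False``.  Returns a
    DataFrame indexed by candidate with columns log2fc, t, p, p_adj,
    passed_pm_mm_filter, has_mm, n_spots_used, de_call (and biotype when a
    mapping is supplied).
    """
    case, control = conditions
    filt = pm_mm_filter(scans, sheet, conditions)

    scan_by_id = {s.array_id: s for s in scans}
    ma_list = []
    for row in sheet.itertuples():
        scan = scan_by_id[row.array_id]
        ma = make_ma(scan, case, control)
        ma_list.append(normalize_within(ma))
    ma_list = normalize_between(ma_list)

    n_spots = (
        pd.concat([ma.spots[ma.spots["pair_role"] != "MM"][["Name"]] for ma in ma_list])
        .groupby("Name")
        .size()
    )
    keep = set(filt.index[filt["passed"]])
    kept_ma = [
        MAMatrix(ma.array_id, ma.spots[ma.spots["Name"].isin(keep)].reset_index(drop=True))
        for ma in ma_list
    ]
    fit = fit_dyeswap(kept_ma, sheet, dup_method)
    _, moderated = ebayes(fit)
    moderated["p_adj"] = bh_adjust(moderated["p"])

    out = filt.copy()
    out = out.rename(columns={"passed": "passed_pm_mm_filter"})
    for col in ("beta", "t", "p", "p_adj"):
        out[col] = moderated[col].reindex(out.index)
    out = out.rename(columns={"beta": "log2fc"})
    out["n_spots_used"] = n_spots.reindex(out.index).fillna(0).astype(int)
    out["de_call"] = (out["p_adj"] < alpha).fillna(False)
    if biotypes:
        out.insert(0, "biotype", pd.Series(biotypes).reindex(out.index).fillna("unknown"))
    return out
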