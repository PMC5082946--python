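"""Consensus differential expression: two independent engines intersected.

Each contrast compares two duplicated groups at one time point:

* infected vs uninfected with the light regime held fixed, or
* dark vs light with the infection status held fixed,

for sense or antisense transcripts separately.  Two engines are run:

* a parametric negative-binomial Wald test on size-factor-normalized
  counts, with a per-gene method-of-moments dispersion shrunk toward a
  fitted mean-dispersion trend (a0/mu + a1);
* a nonparametric noise-distribution test: the per-gene signal
  (M = log2 ratio of group means, D = absolute difference of group means,
  on normalized abundances) is ranked against an empirical noise cloud
  assembled from all within-condition replicate comparisons; q is the
  fraction of noise points dominated by the signal.

A gene is a consensus DEG when q > 0.95, BH-adjusted parametric p < 0.2,
|log2FC| >= 0.4 (infected vs uninfected) or >= 1.5 (dark vs light), and
the summed normalized abundance over the contrast's four samples is
>= 500 (sense) or >= 100 (antisense).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

Q_THRESHOLD = 0.95
PADJ_THRESHOLD = 0.2
LFC_THRESHOLDS = {"infected_vs_uninfected": 0.4, "dark_vs_light": 1.5}
ABUNDANCE_FLOORS = {"sense": 500.0, "antisense": 100.0}
PSEUDOCOUNT = 0.5


class DEError(ValueError):
    pass


@dataclass(frozen=True)
class Contrast:
    """One two-group comparison at one time point.

    ``kind='infected_vs_uninfected'`` with ``fixed_level`` in
    {'light','dark'}; or ``kind='dark_vs_light'`` with ``fixed_level`` in
    {'infected','uninfected'}.  The first-named group is the treatment
    (numerator of the fold change)."""

    kind: str
    fixed_level: str
    time_h: float
    orientation: str = "sense"

    def __post_init__(self) -> None:
        if self.kind not in LFC_THRESHOLDS:
            raise DEError(f"unknown contrast kind {self.kind!r}")
        valid_fixed = (
            ("light", "dark")
            if self.kind == "infected_vs_uninfected"
            else ("infected", "uninfected")
        )
        if self.fixed_level not in valid_fixed:
            raise DEError(
                f"fixed level {self.fixed_level!r} invalid for {self.kind}"
            )
        if self.orientation not in ("sense", "antisense"):
            raise DEError(f"bad orientation {self.orientation!r}")

    @property
    def lfc_threshold(self) -> float:
        return LFC_THRESHOLDS[self.kind]

    @property
    def abundance_floor(self) -> float:
        return ABUNDANCE_FLOORS[self.orientation]

    def groups(self, samples: pd.DataFrame) -> tuple[list[str], list[str]]:
        """(treatment sample ids, baseline sample ids) at this time point."""
        at_t = samples[samples["time_h"] == self.time_h]
        if self.kind == "infected_vs_uninfected":
            fixed = at_t[at_t["light"] == self.fixed_level]
            treat = fixed[fixed["infected"] == "infected"]
            base = fixed[fixed["infected"] == "uninfected"]
        else:
            fixed = at_t[at_t["infected"] == self.fixed_level]
            treat = fixed[fixed["light"] == "dark"]
            base = fixed[fixed["light"] == "light"]
        if len(treat) < 2 or len(base) < 2:
            raise DEError(
                f"contrast {self} needs >= 2 replicates per group "
                f"({len(treat)} vs {len(base)} found)"
            )
        return list(treat.index), list(base.index)

    def label(self) -> str:
        return f"{self.kind}|{self.fixed_level}|t{self.time_h:g}|{self.orientation}"


# ---------------------------------------------------------------------------
# parametric engine


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios size factors.

    The reference is the per-gene geometric mean across samples, computed
    over genes with no zero count; each sample's factor is the median of
    its ratios to the reference.  If no zero-free gene exists, falls back
    to total-count ratios (normalized to geometric mean 1)."""
    if counts.shape[1] < 2:
        raise DEError("need >= 2 samples")
    arr = counts.to_numpy(dtype=float)
    nonzero = (arr > 0).all(axis=1)
    if nonzero.sum() == 0:
        import warnings

        warnings.warn(
            "no zero-free genes; falling back to total-count size factors",
            stacklevel=2,
        )
        totals = arr.sum(axis=0)
        if (totals <= 0).any():
            raise DEError("sample with zero total counts")
        factors = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(factors, index=counts.columns)
    sub = arr[nonzero]
    log_geo = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_geo[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns)


def _dispersion_trend(mu: np.ndarray, alpha_mom: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0/mu + a1 by least squares on moment estimates."""
    ok = (mu > 0) & np.isfinite(alpha_mom)
    if ok.sum() < 2:
        return np.full_like(mu, np.nanmedian(np.where(ok, alpha_mom, np.nan)) or 0.1)
    x = np.column_stack([1.0 / mu[ok], np.ones(ok.sum())])
    coef, *_ = np.linalg.lstsq(x, alpha_mom[ok], rcond=None)
    a0, a1 = max(coef[0], 0.0), max(coef[1], 1e-8)
    with np.errstate(divide="ignore"):
        trend = a0 / np.maximum(mu, 1e-8) + a1
    return trend


def nb_test(
    counts: pd.DataFrame,
    treat_ids: list[str],
    base_ids: list[str],
    shrinkage: float = 0.5,
) -> pd.DataFrame:
    """Negative-binomial Wald test on 2 vs 2 samples.

    Returns per-gene log2FC (treatment over baseline, pseudocount 0.5 on
    size-factor-normalized means), Wald p and BH-adjusted p.  All-zero
    genes get (0, 1)."""
    sub = counts[treat_ids + base_ids]
    sf = size_factors(sub)
    norm = sub.div(sf, axis=1)
    y1 = norm[treat_ids].to_numpy(dtype=float)
    y2 = norm[base_ids].to_numpy(dtype=float)
    m1 = y1.mean(axis=1)
    m2 = y2.mean(axis=1)
    log2fc = np.log2((m1 + PSEUDOCOUNT) / (m2 + PSEUDOCOUNT))

    # method-of-moments dispersion pooled across both groups
    mu_all = np.concatenate([y1, y2], axis=1).mean(axis=1)
    var_within = 0.5 * (y1.var(axis=1, ddof=1) + y2.var(axis=1, ddof=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (var_within - mu_all) / mu_all**2
    alpha_mom = np.clip(alpha_mom, 1e-8, 10.0)
    trend = np.clip(_dispersion_trend(mu_all, alpha_mom), 1e-8, 10.0)
    # shrink toward the trend but never below it: per-gene moment estimates
    # at duplicate depth are so noisy that allowing them to pull the
    # dispersion under the trend makes the null anti-conservative
    alpha = np.maximum(trend, shrinkage * alpha_mom + (1.0 - shrinkage) * trend)

    n1, n2 = y1.shape[1], y2.shape[1]
    ln2sq = np.log(2.0) ** 2
    var_m1 = (m1 + alpha * m1**2) / n1
    var_m2 = (m2 + alpha * m2**2) / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        se_sq = var_m1 / ((m1 + PSEUDOCOUNT) ** 2 * ln2sq) + var_m2 / (
            (m2 + PSEUDOCOUNT) ** 2 * ln2sq
        )
        z = log2fc / np.sqrt(se_sq)
    p = 2.0 * stats.norm.sf(np.abs(z))

    allzero = (m1 == 0) & (m2 == 0)
    log2fc[allzero] = 0.0
    p[allzero] = 1.0
    p = np.clip(p, 0.0, 1.0)
    padj = benjamini_hochberg(p)
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "padj": padj,
         "mean_treat": m1, "mean_base": m2},
        index=counts.index,
    )


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (FDR)."""
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# nonparametric engine


def noise_test(
    values: pd.DataFrame,
    treat_ids: list[str],
    base_ids: list[str],
) -> pd.DataFrame:
    """Empirical noise-distribution test on normalized abundances.

    Signal per gene: M = log2((m1+0.5)/(m2+0.5)), D = |m1 - m2| on group
    means.  Noise: the same statistics computed between replicates *within*
    each group, pooled across genes and both groups.  q is the fraction of
    noise points (M0, D0) with |M| >= |M0| and D >= D0."""
    if len(treat_ids) < 2 or len(base_ids) < 2:
        raise DEError("need >= 2 replicates per group")
    a = values[treat_ids].to_numpy(dtype=float)
    b = values[base_ids].to_numpy(dtype=float)
    m1 = a.mean(axis=1)
    m2 = b.mean(axis=1)
    m_sig = np.log2((m1 + PSEUDOCOUNT) / (m2 + PSEUDOCOUNT))
    d_sig = np.abs(m1 - m2)

    noise_m = []
    noise_d = []
    for grp in (a, b):
        n_rep = grp.shape[1]
        for i in range(n_rep):
            for j in range(i + 1, n_rep):
                noise_m.append(
                    np.log2((grp[:, i] + PSEUDOCOUNT) / (grp[:, j] + PSEUDOCOUNT))
                )
                noise_d.append(np.abs(grp[:, i] - grp[:, j]))
    m0 = np.abs(np.concatenate(noise_m))
    d0 = np.concatenate(noise_d)

    abs_m = np.abs(m_sig)
    # q[g] = mean over noise points of (|M_g| >= |M0| and D_g >= D0)
    dominated = (abs_m[:, None] >= m0[None, :]) & (d_sig[:, None] >= d0[None, :])
    q = dominated.mean(axis=1)
    return pd.DataFrame(
        {"M": m_sig, "D": d_sig, "q": q, "mean_treat": m1, "mean_base": m2},
        index=values.index,
    )


# ---------------------------------------------------------------------------
# consensus


def consensus_degs(
    nb: pd.DataFrame,
    noise: pd.DataFrame,
    norm_values: pd.DataFrame,
    contrast: Contrast,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Intersect the two engines under the published thresholds.

    ``norm_values`` must be the normalized abundances of the tested genes
    (same index as the engine outputs); the abundance filter sums them over
    the contrast's four samples."""
    if not nb.index.equals(noise.index):
        raise DEError("engine outputs are not aligned")
    treat_ids, base_ids = contrast.groups(samples)
    total_norm = norm_values[treat_ids + base_ids].sum(axis=1)
    if not total_norm.index.equals(nb.index):
        raise DEError("normalized matrix not aligned with engine outputs")

    out = pd.DataFrame(index=nb.index)
    out["log2fc"] = nb["log2fc"]
    out["M"] = noise["M"]
    out["D"] = noise["D"]
    out["q"] = noise["q"]
    out["p"] = nb["p"]
    out["padj"] = nb["padj"]
    out["total_norm"] = total_norm
    out["passes_q"] = noise["q"] > Q_THRESHOLD
    out["passes_padj"] = nb["padj"] < PADJ_THRESHOLD
    out["passes_lfc"] = nb["log2fc"].abs() >= contrast.lfc_threshold
    out["passes_abundance"] = total_norm >= contrast.abundance_floor
    out["deg"] = (
        out["passes_q"]
        & out["passes_padj"]
        & out["passes_lfc"]
        & out["passes_abundance"]
    )
    out["direction"] = np.where(out["log2fc"] >= 0, "enriched", "diminished")
    out["contrast"] = contrast.label()
    out["time_h"] = contrast.time_h
    out["orientation"] = contrast.orientation
    return out


def run_contrast(
    counts: pd.DataFrame,
    norm_values: pd.DataFrame,
    samples: pd.DataFrame,
    contrast: Contrast,
) -> pd.DataFrame:
    """Run both engines and the consensus for one contrast.

    ``counts`` are raw counts and ``norm_values`` normalized abundances,
    both already restricted to one orientation's rows (plain gene index)."""
    treat_ids, base_ids = contrast.groups(samples)
    nb = nb_test(counts, treat_ids, base_ids)
    noise = noise_test(norm_values, treat_ids, base_ids)
    return consensus_degs(nb, noise, norm_values, contrast, samples)


def all_contrasts(
    samples: pd.DataFrame, orientations: tuple[str, ...] = ("sense", "antisense")
) -> list[Contrast]:
    """Every (kind, fixed level, time point, orientation) the design allows."""
    out = []
    times = sorted(samples["time_h"].unique())
    for orientation in orientations:
        for t in times:
            for fixed in ("light", "dark"):
                if fixed in set(samples["light"]):
                    out.append(
                        Contrast("infected_vs_uninfected", fixed, t, orientation)
                    )
            for fixed in ("infected", "uninfected"):
                if fixed in set(samples["infected"]):
                    out.append(Contrast("dark_vs_light", fixed, t, orientation))
    return out
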