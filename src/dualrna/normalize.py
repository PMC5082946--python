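"""Displacement-aware dual-pool normalization.

As infection proceeds, phage transcripts grow to dominate the RNA pool and
proportionally displace host transcripts, so a host gene can lose library
share without any change in host transcription.  The remedy is two
normalization pools per sample:

* host genes are length-normalized and rescaled so the *host-only* pool
  totals 1,000,000 ("RPKM" on the host pool) — host values are then
  insensitive to phage take-over;
* phage genes are rescaled on the *combined* host+phage pool (also
  totalling 1,000,000), so phage values track the true rise of phage
  transcription as a fraction of the whole pool.

Both orientations of a feature are normalized inside the same pools.
rRNA must already be removed; intergenic features are excluded from the
pools and dropped from the normalized matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import Annotation, HOST, PHAGE
from .counting import StrandedCountTable

POOL_SCALE = 1_000_000.0


class NormalizationError(ValueError):
    pass


def _feature_meta(table: StrandedCountTable, ann: Annotation) -> dict:
    meta = {f.feature_id: f for f in ann.features}
    fids = set(table.counts.index.get_level_values("feature_id"))
    if not fids <= set(meta):
        meta = {f.feature_id: f for f in ann.with_intergenic().features}
        missing = fids - set(meta)
        if missing:
            raise NormalizationError(f"unannotated features {sorted(missing)[:5]}")
    return meta


@dataclass
class NormalizedMatrix:
    """Length- and depth-normalized abundances with their pool tags."""

    values: pd.DataFrame  # indexed like StrandedCountTable
    pool: pd.Series  # per row: 'host_pool' | 'combined_pool'
    pool_totals: pd.DataFrame  # per sample: host_rate, combined_rate (pre-scaling)
    samples: pd.DataFrame
    scheme: str = "dual"

    def host_values(self) -> pd.DataFrame:
        return self.values.loc[self.pool == "host_pool"]

    def phage_values(self) -> pd.DataFrame:
        return self.values.loc[self.pool == "combined_pool"]

    def to_tsv(self, path: str) -> None:
        df = self.values.reset_index()
        df.insert(2, "pool", self.pool.to_numpy())
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def normalize_dual(
    table: StrandedCountTable,
    ann: Annotation,
    scheme: str = "dual",
) -> NormalizedMatrix:
    """Length-normalize and pool-rescale a stranded count table.

    ``scheme='dual'`` (default) rescales host rows on the host pool and
    phage rows on the combined pool, each to a total of 1e6.
    ``scheme='classic'`` divides length-normalized rates by (pool mapped
    counts / 1e6) without forcing the sum — classic RPKM for comparison.
    """
    if scheme not in ("dual", "classic"):
        raise NormalizationError(f"unknown scheme {scheme!r}")
    meta = _feature_meta(table, ann)
    fids = table.counts.index.get_level_values("feature_id")
    classes = np.array([meta[f].feature_class for f in fids])
    organisms = np.array([meta[f].organism for f in fids])
    if (classes == "rRNA")[organisms == HOST].any():
        raise NormalizationError("host rRNA rows present; remove rRNA first")

    keep = classes != "intergenic"
    counts = table.counts.loc[keep]
    organisms = organisms[keep]
    lengths_kb = np.array(
        [meta[f].length_bp / 1000.0 for f in counts.index.get_level_values("feature_id")]
    )

    rates = counts.div(1.0).mul(1.0 / lengths_kb, axis=0)

    host_rows = organisms == HOST
    phage_rows = organisms == PHAGE
    host_rate_total = rates.loc[host_rows].sum(axis=0)
    combined_rate_total = rates.sum(axis=0)

    if (host_rate_total <= 0).any():
        bad = host_rate_total.index[host_rate_total <= 0].tolist()
        raise NormalizationError(f"zero host pool total in samples {bad}")

    values = pd.DataFrame(
        np.nan, index=counts.index, columns=counts.columns, dtype=float
    )
    if scheme == "dual":
        values.loc[host_rows] = (
            rates.loc[host_rows].div(host_rate_total, axis=1) * POOL_SCALE
        )
        values.loc[phage_rows] = (
            rates.loc[phage_rows].div(combined_rate_total, axis=1) * POOL_SCALE
        )
    else:  # classic RPKM: per-million of pool mapped counts
        host_count_total = counts.loc[host_rows].sum(axis=0)
        combined_count_total = counts.sum(axis=0)
        values.loc[host_rows] = rates.loc[host_rows].div(
            host_count_total / POOL_SCALE, axis=1
        )
        values.loc[phage_rows] = rates.loc[phage_rows].div(
            combined_count_total / POOL_SCALE, axis=1
        )

    pool = pd.Series(
        np.where(host_rows, "host_pool", "combined_pool"), index=counts.index
    )
    pool_totals = pd.DataFrame(
        {"host_rate": host_rate_total, "combined_rate": combined_rate_total}
    )
    return NormalizedMatrix(
        values=values,
        pool=pool,
        pool_totals=pool_totals,
        samples=table.samples,
        scheme=scheme,
    )


def phage_fraction(table: StrandedCountTable, ann: Annotation) -> pd.Series:
    """Per-sample phage share of all (post-rRNA-removal) counts."""
    meta = _feature_meta(table, ann)
    fids = table.counts.index.get_level_values("feature_id")
    classes = np.array([meta[f].feature_class for f in fids])
    organisms = np.array([meta[f].organism for f in fids])
    if (classes == "rRNA")[organisms == HOST].any():
        raise NormalizationError("host rRNA rows present; remove rRNA first")
    keep = classes != "intergenic"
    counts = table.counts.loc[keep]
    total = counts.sum(axis=0)
    if (total <= 0).any():
        bad = total.index[total <= 0].tolist()
        raise NormalizationError(f"zero count total in samples {bad}")
    phage = counts.loc[organisms[keep] == PHAGE].sum(axis=0)
    return phage / total


def antisense_sense_ratio(
    norm: NormalizedMatrix,
    pseudocount: float = 0.1,
    flag_threshold: float = 10.0,
) -> pd.DataFrame:
    """Per-gene ratio of across-sample average antisense to sense abundance.

    The denominator is floored at ``pseudocount`` normalized units so genes
    with no sense expression but real antisense signal get a large, finite
    ratio.  Genes above ``flag_threshold`` are flagged (high-antisense
    listing).
    """
    sense = norm.values.xs("sense", level="orientation").mean(axis=1)
    anti = norm.values.xs("antisense", level="orientation").mean(axis=1)
    anti = anti.reindex(sense.index).fillna(0.0)
    ratio = anti / np.maximum(sense, pseudocount)
    return pd.DataFrame(
        {
            "sense_mean": sense,
            "antisense_mean": anti,
            "ratio": ratio,
            "high_antisense": ratio > flag_threshold,
        }
    )
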