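"""Strand-specific paired-end read counting.

Rules applied, in order:

1. Only primary, mapped records are considered.
2. A record is *perfect* iff it aligns full length with zero mismatches:
   CIGAR consisting solely of M and NM tag equal to 0.  Records without an
   NM tag cannot be verified and are discarded.
3. The transcribed strand is inferred from the dUTP second-strand protocol:
   mate 1 carries the transcript strand, mate 2 its complement (flip with
   ``mate1_is_transcript=False`` for the opposite library dialect).
4. A mate overlapping a feature contributes (feature, orientation) where
   orientation is sense when the transcribed strand equals the feature
   strand.  Intergenic features (strand 'both') record '+'-strand
   transcription as sense, '-'-strand as antisense.
5. The two mates of a template are collapsed: each distinct
   (feature, orientation) hit by either mate is incremented once — a pair
   inside one ORF counts one transcript for it; a pair whose mates land in
   different ORFs counts once for each.
6. Host 16S/23S rRNA rows are removed before filtering or normalization.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .annotations import Annotation, FeatureAnnotation, HOST

ORIENTATIONS = ("sense", "antisense")

SAMPLE_COLUMNS = ("time_h", "light", "infected", "replicate")


class CountingError(ValueError):
    pass


@dataclass
class StrandedCountTable:
    """Integer counts indexed by (feature_id, orientation), one column per
    sample, plus the sample sheet (time_h, light, infected, replicate)."""

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not (self.counts.dtypes == np.int64).all():
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise CountingError("negative counts")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise CountingError(f"sample sheet lacks columns {missing}")
        extra = set(self.counts.columns) - set(self.samples.index)
        if extra:
            raise CountingError(f"samples without metadata: {sorted(extra)}")

    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def organism_of(self, ann: Annotation) -> pd.Series:
        org = {f.feature_id: f.organism for f in ann.features}
        return pd.Series(
            [org[f] for f in self.counts.index.get_level_values("feature_id")],
            index=self.counts.index,
        )

    def to_tsv(self, path: str, ann: Annotation | None = None) -> None:
        df = self.counts.reset_index()
        if ann is not None:
            meta = {f.feature_id: (f.organism, f.feature_class) for f in ann.features}
            if not set(df["feature_id"]) <= set(meta):
                # table carries intergenic rows the caller's annotation lacks
                meta = {
                    f.feature_id: (f.organism, f.feature_class)
                    for f in ann.with_intergenic().features
                }
            df.insert(1, "organism", [meta[f][0] for f in df["feature_id"]])
            df.insert(2, "feature_class", [meta[f][1] for f in df["feature_id"]])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path: str, sample_sheet_path: str) -> "StrandedCountTable":
        df = pd.read_csv(counts_path, sep="\t")
        df = df.drop(columns=[c for c in ("organism", "feature_class") if c in df])
        df = df.set_index(["feature_id", "orientation"])
        samples = pd.read_csv(sample_sheet_path, sep="\t").set_index("sample_id")
        return cls(counts=df, samples=samples)


@dataclass
class CountingLog:
    templates_seen: int = 0
    templates_retained: int = 0
    discarded_imperfect: int = 0
    discarded_no_nm: int = 0
    discarded_unmapped: int = 0

    def as_text(self) -> str:
        return (
            f"templates_seen\t{self.templates_seen}\n"
            f"templates_retained\t{self.templates_retained}\n"
            f"discarded_imperfect\t{self.discarded_imperfect}\n"
            f"discarded_no_nm\t{self.discarded_no_nm}\n"
            f"discarded_unmapped\t{self.discarded_unmapped}\n"
        )


def is_perfect(read: pysam.AlignedSegment) -> bool:
    """True iff the record is a full-length exact match.

    Requires a CIGAR of only M operations (no indels, no soft/hard clips)
    and edit distance zero (NM tag).  Raises KeyError if NM is absent —
    callers decide how to treat unverifiable records.
    """
    if read.is_unmapped or read.cigartuples is None:
        return False
    if any(op != 0 for op, _ in read.cigartuples):  # 0 = M
        return False
    return read.get_tag("NM") == 0


def transcribed_strand(read: pysam.AlignedSegment, mate1_is_transcript: bool = True) -> str:
    """Strand of the RNA molecule the record derives from."""
    read_strand = "-" if read.is_reverse else "+"
    is_mate1 = read.is_read1 or not read.is_paired
    if is_mate1 == mate1_is_transcript:
        return read_strand
    return "-" if read_strand == "+" else "+"


class FeatureIndex:
    """Interval lookup of features per replicon."""

    def __init__(self, ann: Annotation, include_intergenic: bool = True):
        if include_intergenic and not any(
            f.feature_class == "intergenic" for f in ann.features
        ):
            ann = ann.with_intergenic()
        self.ann = ann
        self.trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for f in ann.features:
            self.trees[f.replicon][f.start : f.end] = f

    def overlapping(self, replicon: str, start: int, end: int) -> list[FeatureAnnotation]:
        return sorted(
            (iv.data for iv in self.trees[replicon][start:end]),
            key=lambda f: (f.start, f.feature_id),
        )


def assign_mate(
    read: pysam.AlignedSegment,
    index: FeatureIndex,
    mate1_is_transcript: bool = True,
) -> set[tuple[str, str]]:
    """All (feature_id, orientation) keys one perfect mate contributes to."""
    strand = transcribed_strand(read, mate1_is_transcript)
    hits = set()
    for f in index.overlapping(
        read.reference_name, read.reference_start, read.reference_end
    ):
        if f.strand == "both":
            orientation = "sense" if strand == "+" else "antisense"
        else:
            orientation = "sense" if strand == f.strand else "antisense"
        hits.add((f.feature_id, orientation))
    return hits


def collapse_pair(
    hits_mate1: set[tuple[str, str]], hits_mate2: set[tuple[str, str]]
) -> Counter:
    """One increment per distinct (feature, orientation) hit by either mate."""
    merged = set(hits_mate1) | set(hits_mate2)
    return Counter(merged)


def count_sample(
    sam_path: str,
    ann: Annotation,
    mate1_is_transcript: bool = True,
) -> tuple[pd.Series, CountingLog]:
    """Count one SAM/BAM file into a (feature_id, orientation) column.

    Templates are grouped by query name (the file need not be sorted);
    imperfect and unverifiable mates are dropped individually, so a pair
    with one perfect mate still contributes that mate's hits.
    """
    index = FeatureIndex(ann)
    log = CountingLog()

    known_replicons = set(ann.replicon_lengths)
    templates: dict[str, list] = defaultdict(list)
    mode = "rb" if str(sam_path).endswith(".bam") else "r"
    with pysam.AlignmentFile(sam_path, mode, check_sq=False) as fh:
        header_refs = set(fh.references)
        unknown = header_refs - known_replicons
        if unknown:
            raise CountingError(
                f"SAM header replicons {sorted(unknown)} absent from annotation"
            )
        for read in fh.fetch(until_eof=True):
            if read.is_secondary or read.is_supplementary:
                continue
            templates[read.query_name].append(read)

    counts: Counter = Counter()
    for qname, reads in templates.items():
        log.templates_seen += 1
        hits_per_mate = []
        any_mapped = False
        any_perfect = False
        for read in reads:
            if read.is_unmapped:
                continue
            any_mapped = True
            try:
                perfect = is_perfect(read)
            except KeyError:
                log.discarded_no_nm += 1
                continue
            if not perfect:
                continue
            any_perfect = True
            hits_per_mate.append(assign_mate(read, index, mate1_is_transcript))
        if not any_mapped:
            log.discarded_unmapped += 1
            continue
        if not any_perfect:
            log.discarded_imperfect += 1
            continue
        log.templates_retained += 1
        pair_hits = collapse_pair(
            hits_per_mate[0], hits_per_mate[1] if len(hits_per_mate) > 1 else set()
        )
        counts.update(pair_hits)

    full_ann = index.ann
    idx = pd.MultiIndex.from_product(
        [full_ann.ids(), list(ORIENTATIONS)], names=["feature_id", "orientation"]
    )
    col = pd.Series(0, index=idx, dtype=np.int64)
    for key, n in counts.items():
        col.loc[key] = n
    return col, log


def count_samples(
    sam_paths: dict[str, str],
    ann: Annotation,
    samples: pd.DataFrame,
    mate1_is_transcript: bool = True,
) -> tuple[StrandedCountTable, dict[str, CountingLog]]:
    """Count several samples into one table (columns ordered as in samples)."""
    cols = {}
    logs = {}
    for sid in samples.index:
        cols[sid], logs[sid] = count_sample(
            sam_paths[sid], ann, mate1_is_transcript
        )
    counts = pd.DataFrame(cols)[list(samples.index)]
    counts.index.names = ["feature_id", "orientation"]
    return StrandedCountTable(counts=counts, samples=samples), logs


def remove_rrna(
    table: StrandedCountTable, ann: Annotation
) -> tuple[StrandedCountTable, pd.Series]:
    """Drop host 16S/23S rRNA rows (both orientations).

    Returns the filtered table and the per-sample fraction of counts that
    was removed.  A table without rRNA rows passes through unchanged with
    zero removed fractions.
    """
    rrna_ids = {
        f.feature_id
        for f in ann.features
        if f.feature_class == "rRNA" and f.organism == HOST
    }
    in_table = table.counts.index.get_level_values("feature_id").isin(rrna_ids)
    total = table.counts.sum(axis=0)
    removed = table.counts.loc[in_table].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (removed / total).fillna(0.0)
    filtered = table.counts.loc[~in_table]
    return StrandedCountTable(counts=filtered, samples=table.samples), frac
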