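"""Genomic feature annotations for a two-replicon (host + phage) system.

Features are stored in 0-based half-open coordinates internally; GFF3 and
GenBank use 1-based inclusive coordinates at the file boundary.  Intergenic
regions are not read from file: they are derived as the complement of the
annotated features on each replicon and carry strand ``both`` (reads hitting
them are tallied per transcribed strand).
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO

HOST = "host"
PHAGE = "phage"

FEATURE_CLASSES = ("ORF", "rRNA", "tRNA", "intergenic")

#: GFF3/GenBank feature types mapped onto the four internal classes.
_TYPE_MAP = {
    "CDS": "ORF",
    "gene": "ORF",
    "ORF": "ORF",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
}


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class FeatureAnnotation:
    """A located, stranded genomic feature tagged by organism.

    Coordinates are 0-based half-open.  ``strand`` is '+', '-' or 'both'
    (the latter only for intergenic complement features).
    """

    feature_id: str
    organism: str  # 'host' | 'phage'
    replicon: str
    start: int
    end: int
    strand: str
    feature_class: str  # 'ORF' | 'rRNA' | 'tRNA' | 'intergenic'
    product: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"{self.feature_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "both"):
            raise AnnotationError(f"{self.feature_id}: bad strand {self.strand!r}")
        if self.feature_class not in FEATURE_CLASSES:
            raise AnnotationError(
                f"{self.feature_id}: bad feature class {self.feature_class!r}"
            )
        if self.organism not in (HOST, PHAGE):
            raise AnnotationError(f"{self.feature_id}: bad organism {self.organism!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class Annotation:
    """All features of one run, plus replicon lengths keyed by replicon name."""

    features: list[FeatureAnnotation] = field(default_factory=list)
    replicon_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for f in self.features:
            if f.feature_id in seen:
                raise AnnotationError(f"duplicate feature id {f.feature_id!r}")
            seen.add(f.feature_id)

    def by_class(self, *classes: str) -> list[FeatureAnnotation]:
        return [f for f in self.features if f.feature_class in classes]

    def by_organism(self, organism: str) -> list[FeatureAnnotation]:
        return [f for f in self.features if f.organism == organism]

    def get(self, feature_id: str) -> FeatureAnnotation:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def with_intergenic(self) -> "Annotation":
        """Return a copy whose features include the intergenic complement."""
        extra = intergenic_complement(self.features, self.replicon_lengths)
        return Annotation(self.features + extra, dict(self.replicon_lengths))


def intergenic_complement(
    features: Sequence[FeatureAnnotation], replicon_lengths: dict[str, int]
) -> list[FeatureAnnotation]:
    """Tile the unannotated portion of each replicon with intergenic features.

    The complement ignores strand: any base not covered by an annotated
    feature (either strand) becomes part of an intergenic region with
    strand 'both'.  Organism is inherited from the replicon's features.
    """
    out: list[FeatureAnnotation] = []
    for replicon, length in replicon_lengths.items():
        feats = [f for f in features if f.replicon == replicon]
        if not feats:
            continue
        organism = feats[0].organism
        ivals = sorted((f.start, f.end) for f in feats)
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        cursor = 0
        n = 0
        for s, e in merged:
            if s > cursor:
                out.append(
                    FeatureAnnotation(
                        feature_id=f"{replicon}_ig{n:04d}",
                        organism=organism,
                        replicon=replicon,
                        start=cursor,
                        end=s,
                        strand="both",
                        feature_class="intergenic",
                    )
                )
                n += 1
            cursor = max(cursor, e)
        if cursor < length:
            out.append(
                FeatureAnnotation(
                    feature_id=f"{replicon}_ig{n:04d}",
                    organism=organism,
                    replicon=replicon,
                    start=cursor,
                    end=length,
                    strand="both",
                    feature_class="intergenic",
                )
            )
    return out


def _classify(ftype: str) -> str | None:
    return _TYPE_MAP.get(ftype)


def load_annotation(path: str, organism: str, fmt: str | None = None) -> Annotation:
    """Load features from GFF3 or GenBank flat file.

    Parameters
    ----------
    path:
        Input file.  Format is sniffed from the extension unless ``fmt``
        ('gff3' or 'genbank') is given.
    organism:
        'host' or 'phage'; applied to every feature.

    The returned annotation does NOT include intergenic features; call
    :meth:`Annotation.with_intergenic` to add the complement.
    """
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        if ext in (".gff", ".gff3"):
            fmt = "gff3"
        elif ext in (".gb", ".gbk", ".gbff", ".genbank"):
            fmt = "genbank"
        else:
            raise AnnotationError(f"cannot infer annotation format from {path!r}")
    if fmt == "gff3":
        return _load_gff3(path, organism)
    if fmt == "genbank":
        return _load_genbank(path, organism)
    raise AnnotationError(f"unknown annotation format {fmt!r}")


def _load_gff3(path: str, organism: str) -> Annotation:
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, name, start, end = line.split()[:4]
                lengths[name] = int(end)
    features: list[FeatureAnnotation] = []
    for feat in db.all_features(order_by=("seqid", "start")):
        cls = _classify(feat.featuretype)
        if cls is None:
            continue
        fid = feat.attributes.get("ID", [feat.id])[0]
        product = feat.attributes.get("product", [None])[0]
        features.append(
            FeatureAnnotation(
                feature_id=fid,
                organism=organism,
                replicon=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "both",
                feature_class=cls,
                product=product,
            )
        )
    for f in features:
        lengths.setdefault(f.replicon, max(g.end for g in features if g.replicon == f.replicon))
    return Annotation(features, lengths)


def _load_genbank(path: str, organism: str) -> Annotation:
    features: list[FeatureAnnotation] = []
    lengths: dict[str, int] = {}
    for record in SeqIO.parse(path, "genbank"):
        lengths[record.id] = len(record)
        for feat in record.features:
            cls = _classify(feat.type)
            if cls is None:
                continue
            quals = feat.qualifiers
            fid = quals.get("locus_tag", quals.get("gene", [None]))[0]
            if fid is None:
                raise AnnotationError(
                    f"{record.id}: {feat.type} feature without locus_tag/gene"
                )
            product = quals.get("product", [None])[0]
            features.append(
                FeatureAnnotation(
                    feature_id=fid,
                    organism=organism,
                    replicon=record.id,
                    start=int(feat.location.start),  # Biopython is already 0-based
                    end=int(feat.location.end),
                    strand="+" if feat.location.strand >= 0 else "-",
                    feature_class=cls,
                    product=product,
                )
            )
    return Annotation(features, lengths)


_GFF3_TYPE = {"ORF": "CDS", "rRNA": "rRNA", "tRNA": "tRNA", "intergenic": "region"}


def write_gff3(ann: Annotation, path: str, source: str = "dualrna") -> None:
    """Write ORF/rRNA/tRNA features (not the intergenic complement) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name in sorted(ann.replicon_lengths):
            fh.write(f"##sequence-region {name} 1 {ann.replicon_lengths[name]}\n")
        for f in sorted(ann.features, key=lambda f: (f.replicon, f.start)):
            if f.feature_class == "intergenic":
                continue
            attrs = f"ID={f.feature_id};organism={f.organism}"
            if f.product:
                attrs += f";product={f.product}"
            strand = f.strand if f.strand in ("+", "-") else "."
            fh.write(
                "\t".join(
                    [
                        f.replicon,
                        source,
                        _GFF3_TYPE[f.feature_class],
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
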