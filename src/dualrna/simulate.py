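"""Synthetic dual-transcriptome generator.

Emulates the statistical structure of a cyanophage infection time course
sampled in light and dark: 5 time points x {light, dark} x {infected,
uninfected} x 2 replicates = 40 libraries of strand-specific paired-end
counts over a host chromosome and a phage genome.

The generator encodes the study conditions directly:

* phage transcripts rise from ~3% of non-rRNA reads at 0.5 h to ~70% at
  8.5 h in light infection, and stay below 2% in dark infection;
* phage genes follow early / middle / late temporal programs whose
  normalized expression peaks at 0.5 h, 2.5 h and 4.5-8.5 h;
* host responses to infection are diluted by the infected-cell fraction
  f = 1 - exp(-MOI) (Poisson adsorption at MOI 1 leaves ~37% of cells
  uninfected), so a true fold change 2^L is observed as f*2^L + (1-f);
* residual rRNA contamination after duplex-specific-nuclease depletion
  (mean ~14%, range 4-59%) and low-level antisense transcription
  (default 2% of sense, with a small set of high-antisense genes).

Counts are negative-binomial with variance mu + alpha*mu^2.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import Annotation, FeatureAnnotation, AnnotationError, HOST, PHAGE

TIME_POINTS_H = (0.5, 1.5, 2.5, 4.5, 8.5)

LIGHT_LEVELS = ("light", "dark")
INFECTION_LEVELS = ("infected", "uninfected")

#: phage share of non-rRNA transcripts per time point, light infection
LIGHT_PHAGE_FRACTION = {0.5: 0.03, 1.5: 0.10, 2.5: 0.28, 4.5: 0.48, 8.5: 0.70}
#: phage share in dark infection: never above 2%
DARK_PHAGE_FRACTION = {0.5: 0.004, 1.5: 0.007, 2.5: 0.010, 4.5: 0.013, 8.5: 0.015}

ORIENTATIONS = ("sense", "antisense")


class SimulationError(ValueError):
    pass


class SizingError(SimulationError):
    """Requested features do not fit on the replicon."""


@dataclass(frozen=True)
class DEGSpec:
    """One true differential-expression effect.

    ``contrast_kind`` is 'infected_vs_uninfected' or 'dark_vs_light';
    ``fixed_level`` pins the other factor (light/dark, or
    infected/uninfected).  The effect multiplies the gene's mean in the
    *treatment* group (infected, or dark) at the listed time points.
    Infection effects are diluted by the infected-cell fraction before
    they reach the counts; light-shift effects act on every cell.
    """

    gene: str
    contrast_kind: str
    fixed_level: str
    log2fc: float
    time_points: tuple[float, ...]


def _default_curve() -> dict[tuple[str, str], dict[float, float]]:
    curve: dict[tuple[str, str], dict[float, float]] = {}
    curve[("light", "infected")] = dict(LIGHT_PHAGE_FRACTION)
    curve[("dark", "infected")] = dict(DARK_PHAGE_FRACTION)
    curve[("light", "uninfected")] = {t: 0.0 for t in TIME_POINTS_H}
    curve[("dark", "uninfected")] = {t: 0.0 for t in TIME_POINTS_H}
    return curve


@dataclass
class SimulationConfig:
    """Parameters of one synthetic infection experiment.

    Defaults reproduce the study design at sequencing scale: library sizes
    drawn from 1.7-4.1 million mapped pairs.  ``desk_config`` returns the
    same design at 200,000 pairs for fast tests.
    """

    seed: int = 0
    time_points_h: tuple[float, ...] = TIME_POINTS_H
    light_levels: tuple[str, ...] = LIGHT_LEVELS
    infection_levels: tuple[str, ...] = INFECTION_LEVELS
    n_replicates: int = 2
    n_host_genes: int = 2015
    n_phage_genes: int = 200
    library_size_range: tuple[int, int] = (1_700_000, 4_100_000)
    phage_fraction_curve: dict = field(default_factory=_default_curve)
    rrna_fraction_range: tuple[float, float] = (0.04, 0.59)
    rrna_beta_shape: tuple[float, float] = (1.0, 4.5)  # mean ~0.14 on the range
    moi: float = 1.0
    nb_dispersion: float = 0.05
    antisense_rate: float = 0.02
    high_antisense_fraction: float = 0.01
    high_antisense_ratio: float = 20.0
    hypothetical_fraction: float = 0.3
    host_gene_length_bp: tuple[int, int] = (300, 2400)
    phage_gene_length_bp: tuple[int, int] = (200, 1500)
    host_replicon_length: int | None = None
    phage_replicon_length: int | None = None
    deg_spec: tuple[DEGSpec, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.library_size_range
        if lo > hi or lo <= 0:
            raise SimulationError("library_size_range must be 0 < low <= high")
        if self.n_replicates < 2:
            raise SimulationError("need n_replicates >= 2")
        if self.moi < 0:
            raise SimulationError("moi must be >= 0")
        if self.nb_dispersion <= 0:
            raise SimulationError("nb_dispersion must be > 0")
        if not 0 <= self.antisense_rate <= 1:
            raise SimulationError("antisense_rate must be in [0, 1]")
        if not self.light_levels or not self.infection_levels:
            raise SimulationError("empty condition set")
        for (light, infected), curve in self.phage_fraction_curve.items():
            for t, frac in curve.items():
                if not 0.0 <= frac <= 1.0:
                    raise SimulationError(f"phage fraction {frac} outside [0,1]")
                if infected == "uninfected" and frac != 0.0:
                    raise SimulationError(
                        "uninfected conditions must have zero phage fraction"
                    )
        a, b = self.rrna_fraction_range
        if not (0.0 <= a <= b <= 1.0):
            raise SimulationError("rrna_fraction_range must be within [0, 1]")

    @property
    def infected_fraction(self) -> float:
        """Poisson-adsorption infected-cell fraction 1 - exp(-MOI)."""
        return 1.0 - math.exp(-self.moi)

    def conditions(self) -> list[tuple[str, str]]:
        return [(l, i) for l in self.light_levels for i in self.infection_levels]

    def sample_sheet(self) -> pd.DataFrame:
        """Enumerate samples in deterministic order."""
        rows = []
        for light, infected in self.conditions():
            for t in self.time_points_h:
                for rep in range(1, self.n_replicates + 1):
                    sid = f"{light[0].upper()}{infected[0].upper()}_t{t:g}_r{rep}"
                    rows.append(
                        {
                            "sample_id": sid,
                            "time_h": t,
                            "light": light,
                            "infected": infected,
                            "replicate": rep,
                        }
                    )
        return pd.DataFrame(rows).set_index("sample_id")

    def to_flat_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phage_fraction_curve"] = {
            f"{l}:{i}": {str(t): v for t, v in curve.items()}
            for (l, i), curve in self.phage_fraction_curve.items()
        }
        d["deg_spec"] = [dataclasses.asdict(s) for s in self.deg_spec]
        return d


def desk_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Test-scale configuration: same design, 200k read pairs, fewer genes."""
    defaults = dict(
        seed=seed,
        n_host_genes=400,
        n_phage_genes=60,
        library_size_range=(200_000, 200_000),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def default_deg_spec(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[DEGSpec, ...]:
    """A realistic truth set: modest infection responses (|FC| <= ~3, the
    largest the study observed), stronger light-deprivation responses."""
    rng = rng or np.random.default_rng([config.seed, 77])
    n = config.n_host_genes
    genes = [f"host_{i:04d}" for i in range(n)]
    picks = rng.choice(n, size=min(n, max(6, n // 10)), replace=False)
    thirds = np.array_split(picks, 3)
    specs: list[DEGSpec] = []
    lfc3 = math.log2(3.0)
    for g in thirds[0]:
        sign = 1 if rng.random() < 0.5 else -1
        specs.append(
            DEGSpec(genes[g], "infected_vs_uninfected", "light", sign * lfc3,
                    tuple(config.time_points_h))
        )
    for g in thirds[1]:
        sign = 1 if rng.random() < 0.5 else -1
        specs.append(
            DEGSpec(genes[g], "infected_vs_uninfected", "dark", sign * lfc3,
                    tuple(config.time_points_h[2:]))
        )
    for g in thirds[2]:
        sign = 1 if rng.random() < 0.5 else -1
        lfc = float(rng.uniform(1.8, 3.0))
        specs.append(
            DEGSpec(genes[g], "dark_vs_light", "uninfected", sign * lfc,
                    tuple(config.time_points_h))
        )
    return tuple(specs)


@dataclass
class TruthTable:
    """Ground truth of one simulation, for recovery tests."""

    temporal_class: dict[str, str]  # phage gene -> early|middle|late
    true_log2fc: list[dict]  # one record per DEGSpec entry
    phage_fraction: dict[str, float]  # per sample (non-rRNA share)
    rrna_fraction: dict[str, float]  # per sample
    infected_fraction: float

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# annotations


def generate_annotations(config: SimulationConfig) -> Annotation:
    """Lay out non-overlapping ORFs on alternating strands on two replicons.

    The host replicon additionally carries 16S and 23S rRNA genes and three
    tRNAs.  Gene lengths are jittered log-uniformly within the configured
    range; intergenic gaps are 20-200 bp.  Deterministic given the seed.
    """
    if config.n_host_genes < 1 or config.n_phage_genes < 1:
        raise SimulationError("need at least one gene per organism")
    rng = np.random.default_rng([config.seed, 1])

    host_extras = [
        ("host_rrna_16S", "rRNA", 1489, "16S ribosomal RNA"),
        ("host_rrna_23S", "rRNA", 2873, "23S ribosomal RNA"),
        ("host_trna_Arg", "tRNA", 74, "tRNA-Arg"),
        ("host_trna_Gly", "tRNA", 72, "tRNA-Gly"),
        ("host_trna_Leu", "tRNA", 85, "tRNA-Leu"),
    ]

    def layout(
        prefix: str,
        replicon: str,
        organism: str,
        n_genes: int,
        length_range: tuple[int, int],
        extras: list[tuple[str, str, int, str]],
        replicon_length: int | None,
    ) -> tuple[list[FeatureAnnotation], int]:
        lo, hi = length_range
        lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes)).astype(int)
        gaps = rng.integers(20, 201, size=n_genes + len(extras) + 1)
        slots: list[tuple[str, str, int, str | None]] = [
            (f"{prefix}_{i:04d}", "ORF", int(lengths[i]), None) for i in range(n_genes)
        ]
        if extras:
            # scatter rRNA/tRNA features between ORFs at deterministic slots
            positions = np.linspace(1, len(slots) - 1, len(extras)).astype(int)
            for offset, ((fid, cls, ln, product), pos) in enumerate(
                zip(extras, positions)
            ):
                slots.insert(pos + offset, (fid, cls, ln, product))
        feats = []
        cursor = int(gaps[0])
        for i, (fid, cls, ln, product) in enumerate(slots):
            strand = "+" if i % 2 == 0 else "-"
            feats.append(
                FeatureAnnotation(
                    feature_id=fid,
                    organism=organism,
                    replicon=replicon,
                    start=cursor,
                    end=cursor + ln,
                    strand=strand,
                    feature_class=cls,
                    product=product,
                )
            )
            cursor += ln + int(gaps[i + 1])
        total = cursor
        if replicon_length is not None:
            if replicon_length < total:
                raise SizingError(
                    f"{replicon}: {len(slots)} features need {total} bp, "
                    f"replicon is {replicon_length} bp"
                )
            total = replicon_length
        return feats, total

    host_feats, host_len = layout(
        "host", "host_chr", HOST, config.n_host_genes,
        config.host_gene_length_bp, host_extras, config.host_replicon_length,
    )
    phage_feats, phage_len = layout(
        "phage", "phage_chr", PHAGE, config.n_phage_genes,
        config.phage_gene_length_bp, [], config.phage_replicon_length,
    )
    # mark a fraction of host ORFs as hypothetical proteins (reporting filter)
    n_hyp = int(round(config.hypothetical_fraction * config.n_host_genes))
    hyp_idx = set(
        rng.choice(config.n_host_genes, size=n_hyp, replace=False).tolist()
    )
    out: list[FeatureAnnotation] = []
    orf_counter = 0
    for f in host_feats:
        if f.feature_class == "ORF":
            product = (
                "hypothetical protein"
                if orf_counter in hyp_idx
                else f"protein {orf_counter:04d}"
            )
            out.append(dataclasses.replace(f, product=product))
            orf_counter += 1
        else:
            out.append(f)
    out.extend(
        dataclasses.replace(f, product=f"phage protein {i:04d}")
        for i, f in enumerate(phage_feats)
    )
    return Annotation(out, {"host_chr": host_len, "phage_chr": phage_len})


# ---------------------------------------------------------------------------
# counts


def _archetype_curves(time_points: Sequence[float]) -> dict[str, np.ndarray]:
    """Early/middle/late temporal programs as gamma-shaped curves.

    The curves are *within-pool allocation shares*: the fraction of the
    phage transcript pool a gene of that class claims at each time point,
    scaled to peak height 1.  Because the total phage pool share rises
    steeply during light infection, the early and middle shares must decay
    faster than the pool grows for the class's pool-normalized expression
    to peak at the canonical times (early 0.5 h, middle 2.5 h, late at or
    after 4.5 h).  Shapes: early = exponential decay from the first time
    point (gamma k=1, scale 0.5 h); middle = gamma k=6 with mode 2.5 h;
    late = gamma k=2 with mode 4.5 h.
    """
    t = np.asarray(time_points, dtype=float)
    curves = {}
    early = np.exp(-(t - t[0]) / 0.5)
    middle = t**5 * np.exp(-2.0 * t)
    late = t * np.exp(-t / 4.5)
    for name, y in (("early", early), ("middle", middle), ("late", late)):
        curves[name] = y / y.max()
    return curves


def assign_temporal_classes(
    config: SimulationConfig, phage_genes: Sequence[str]
) -> dict[str, str]:
    rng = np.random.default_rng([config.seed, 2])
    classes = ("early", "middle", "late")
    # roughly equal classes with random assignment
    labels = rng.permutation(
        np.array([classes[i % 3] for i in range(len(phage_genes))])
    )
    return dict(zip(phage_genes, labels.tolist()))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with variance mu + alpha*mu^2 (gamma-Poisson)."""
    mean = np.clip(np.asarray(mean, dtype=float), 0.0, None)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, scale=mean * alpha, size=mean.shape)
    return rng.poisson(lam)


def observed_fold_change(true_log2fc: float, moi: float) -> float:
    """Dilution of an infection response by uninfected cells.

    With infected fraction f = 1 - exp(-MOI), the population-level fold
    change of a gene whose infected-cell fold change is 2^L is
    f*2^L + (1-f).
    """
    f = 1.0 - math.exp(-moi)
    return f * (2.0 ** true_log2fc) + (1.0 - f)


def simulate_counts(
    config: SimulationConfig, ann: Annotation
) -> tuple["StrandedCountTable", TruthTable]:
    """Draw the full 40-sample stranded count table plus its ground truth.

    See the module docstring for the generative model.  Phage gene means are
    constructed so that (a) each sample's expected phage share of non-rRNA
    counts equals the configured phage-fraction curve and (b) each gene's
    expected *normalized* profile follows its temporal archetype.
    """
    from .counting import StrandedCountTable  # local import to avoid cycle

    rng = np.random.default_rng([config.seed, 3])
    samples = config.sample_sheet()

    host_orfs = [f for f in ann.by_organism(HOST) if f.feature_class == "ORF"]
    host_trnas = [f for f in ann.by_organism(HOST) if f.feature_class == "tRNA"]
    rrnas = [f for f in ann.by_organism(HOST) if f.feature_class == "rRNA"]
    phage_orfs = [f for f in ann.by_organism(PHAGE) if f.feature_class == "ORF"]
    if not phage_orfs or not host_orfs:
        raise SimulationError("annotation lacks host or phage ORFs")

    host_ids = [f.feature_id for f in host_orfs + host_trnas]
    phage_ids = [f.feature_id for f in phage_orfs]
    known = set(host_ids)  # differential effects are modeled on host genes
    for spec in config.deg_spec:
        if spec.gene not in known:
            raise SimulationError(f"deg_spec references unknown gene {spec.gene!r}")
    seen_pairs = set()
    for spec in config.deg_spec:
        key = (spec.gene, spec.contrast_kind, spec.fixed_level)
        if key in seen_pairs:
            raise SimulationError(f"duplicate deg_spec entry for {key}")
        seen_pairs.add(key)

    # per-gene baseline weights (constant across time)
    host_base = rng.lognormal(mean=0.0, sigma=1.1, size=len(host_ids))
    phage_amp = rng.lognormal(mean=0.0, sigma=0.7, size=len(phage_ids))

    # high-antisense genes (host only)
    n_high = int(round(config.high_antisense_fraction * len(host_ids)))
    high_as = set(
        rng.choice(len(host_ids), size=n_high, replace=False).tolist()
    )
    as_ratio = np.full(len(host_ids), config.antisense_rate)
    for i in high_as:
        as_ratio[i] = config.high_antisense_ratio

    temporal = assign_temporal_classes(config, phage_ids)
    curves = _archetype_curves(config.time_points_h)
    t_index = {t: i for i, t in enumerate(config.time_points_h)}

    f_inf = config.infected_fraction

    rows = pd.MultiIndex.from_product(
        [[f.feature_id for f in host_orfs + host_trnas + rrnas + phage_orfs],
         list(ORIENTATIONS)],
        names=["feature_id", "orientation"],
    )
    counts = pd.DataFrame(0, index=rows, columns=samples.index, dtype=np.int64)

    phage_frac_truth: dict[str, float] = {}
    rrna_frac_truth: dict[str, float] = {}
    host_pos = {g: i for i, g in enumerate(host_ids)}

    a, b = config.rrna_beta_shape
    lo_r, hi_r = config.rrna_fraction_range

    for sid, meta in samples.iterrows():
        light, infected, t = meta["light"], meta["infected"], meta["time_h"]
        lib = int(rng.integers(config.library_size_range[0],
                               config.library_size_range[1] + 1))
        rho = lo_r + (hi_r - lo_r) * rng.beta(a, b)
        phi = config.phage_fraction_curve[(light, infected)][t]

        m_nonrrna = lib * (1.0 - rho)
        phage_total = phi * m_nonrrna
        host_total = (1.0 - phi) * m_nonrrna

        # host sense weights with DEG multipliers
        w = host_base.copy()
        for spec in config.deg_spec:
            if t not in spec.time_points:
                continue
            if spec.contrast_kind == "infected_vs_uninfected":
                in_treatment = infected == "infected" and light == spec.fixed_level
                mult = observed_fold_change(spec.log2fc, config.moi)
            elif spec.contrast_kind == "dark_vs_light":
                in_treatment = light == "dark" and infected == spec.fixed_level
                mult = 2.0 ** spec.log2fc
            else:
                raise SimulationError(f"unknown contrast kind {spec.contrast_kind!r}")
            if in_treatment:
                w[host_pos[spec.gene]] *= mult
        w_as = w * as_ratio
        denom = w.sum() + w_as.sum()
        host_sense_mu = host_total * w / denom
        host_as_mu = host_total * w_as / denom

        # phage genes: allocate the phage pool so that normalized profiles
        # follow the archetypes; weights = archetype value at t x amplitude
        arch = np.array([curves[temporal[g]][t_index[t]] for g in phage_ids])
        pw = arch * phage_amp
        if phage_total > 0 and pw.sum() > 0:
            phage_sense_mu = phage_total * pw / (pw.sum() * (1 + config.antisense_rate))
            phage_as_mu = phage_sense_mu * config.antisense_rate
        else:
            phage_sense_mu = np.zeros(len(phage_ids))
            phage_as_mu = np.zeros(len(phage_ids))

        # rRNA: split residual contamination between 16S and 23S by length
        rr_lens = np.array([f.length_bp for f in rrnas], dtype=float)
        rr_mu = rho * lib * rr_lens / rr_lens.sum() if len(rrnas) else np.array([])

        alpha = config.nb_dispersion
        col = counts[sid].to_numpy().copy()

        def put(ids: list[str], orientation: str, values: np.ndarray) -> None:
            idx = counts.index.get_indexer(
                pd.MultiIndex.from_product([ids, [orientation]])
            )
            col[idx] = values

        put(host_ids, "sense", _nb_draw(rng, host_sense_mu, alpha))
        put(host_ids, "antisense", _nb_draw(rng, host_as_mu, alpha))
        put(phage_ids, "sense", _nb_draw(rng, phage_sense_mu, alpha))
        put(phage_ids, "antisense", _nb_draw(rng, phage_as_mu, alpha))
        if len(rrnas):
            put([f.feature_id for f in rrnas], "sense", _nb_draw(rng, rr_mu, alpha))
        counts[sid] = col

        phage_frac_truth[sid] = float(phi)
        rrna_frac_truth[sid] = float(rho)

    truth = TruthTable(
        temporal_class=temporal,
        true_log2fc=[
            {
                "gene": s.gene,
                "contrast_kind": s.contrast_kind,
                "fixed_level": s.fixed_level,
                "log2fc": s.log2fc,
                "observed_fc": (
                    observed_fold_change(s.log2fc, config.moi)
                    if s.contrast_kind == "infected_vs_uninfected"
                    else 2.0 ** s.log2fc
                ),
                "time_points": list(s.time_points),
            }
            for s in config.deg_spec
        ],
        phage_fraction=phage_frac_truth,
        rrna_fraction=rrna_frac_truth,
        infected_fraction=f_inf,
    )
    return StrandedCountTable(counts=counts, samples=samples), truth


# ---------------------------------------------------------------------------
# SAM fixtures


def _pair_flags(mate1_reverse: bool) -> tuple[int, int]:
    """FLAG values for a proper pair whose mate 1 is on the given strand."""
    base = 0x1 | 0x2  # paired, proper
    f1 = base | 0x40 | (0x10 if mate1_reverse else 0x20)
    f2 = base | 0x80 | (0x20 if mate1_reverse else 0x10)
    return f1, f2


def _make_pair(
    header: "pysam.AlignmentHeader",
    qname: str,
    replicon: str,
    pos1: int,
    pos2: int,
    mate1_reverse: bool,
    read_len: int,
    nm1: int = 0,
    nm2: int = 0,
    replicon2: str | None = None,
):
    import pysam

    f1, f2 = _pair_flags(mate1_reverse)
    out = []
    tid1 = header.get_tid(replicon)
    tid2 = header.get_tid(replicon2 or replicon)
    for flag, tid, pos, mtid, mpos, nm, first in (
        (f1, tid1, pos1, tid2, pos2, nm1, True),
        (f2, tid2, pos2, tid1, pos1, nm2, False),
    ):
        a = pysam.AlignedSegment(header)
        a.query_name = qname
        a.flag = flag
        a.reference_id = tid
        a.reference_start = pos
        a.mapping_quality = 60
        a.cigarstring = f"{read_len}M"
        a.next_reference_id = mtid
        a.next_reference_start = mpos
        a.template_length = 0
        a.query_sequence = "A" * read_len
        a.query_qualities = pysam.qualitystring_to_array("I" * read_len)
        a.set_tag("NM", nm)
        out.append(a)
    return out


def emit_sam_fixture(
    ann: Annotation,
    requests: Mapping[tuple[str, str], int],
    path: str,
    read_len: int = 40,
    n_imperfect_pairs: int = 0,
    cross_pairs: Sequence[tuple[str, str, str]] = (),
    single_mate_requests: Mapping[tuple[str, str], int] | None = None,
    seed: int = 0,
) -> None:
    """Write a SAM file whose perfect pairs reproduce the requested counts.

    ``requests`` maps (feature_id, orientation) to the number of read pairs
    to place fully inside that feature; running the counting rules on the
    output recovers exactly these counts.  ``n_imperfect_pairs`` adds pairs
    with one mismatch in each mate (they must be discarded by the
    perfect-alignment filter).  ``cross_pairs`` entries
    (feature_a, feature_b, orientation) place mate 1 in a and mate 2 in b —
    under the pair-collapsing rule each feature gains one count.
    ``single_mate_requests`` writes templates whose mate 2 is unmapped: the
    surviving perfect mate still contributes one count.
    """
    import pysam

    rng = np.random.default_rng(seed)
    by_id = {f.feature_id: f for f in ann.features}

    def check_len(f: FeatureAnnotation) -> None:
        if f.length_bp < read_len:
            raise SizingError(
                f"{f.feature_id} ({f.length_bp} bp) shorter than read length {read_len}"
            )

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": name, "LN": length}
                for name, length in sorted(ann.replicon_lengths.items())
            ],
        }
    )

    def positions(f: FeatureAnnotation) -> tuple[int, int]:
        lo, hi = f.start, f.end - read_len
        p1 = int(rng.integers(lo, hi + 1))
        p2 = min(p1 + read_len + 10, hi)
        return p1, max(p2, lo)

    def mate1_reverse_for(f: FeatureAnnotation, orientation: str) -> bool:
        if f.strand == "both":
            transcript = "+" if orientation == "sense" else "-"
        else:
            transcript = f.strand if orientation == "sense" else (
                "-" if f.strand == "+" else "+"
            )
        return transcript == "-"

    n = 0
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for (fid, orientation), count in sorted(requests.items()):
            f = by_id[fid]
            check_len(f)
            for _ in range(count):
                p1, p2 = positions(f)
                for a in _make_pair(
                    header, f"pair{n:06d}", f.replicon, p1, p2,
                    mate1_reverse_for(f, orientation), read_len,
                ):
                    out.write(a)
                n += 1
        for fid_a, fid_b, orientation in cross_pairs:
            fa, fb = by_id[fid_a], by_id[fid_b]
            check_len(fa)
            check_len(fb)
            pa, _ = positions(fa)
            pb, _ = positions(fb)
            for a in _make_pair(
                header, f"pair{n:06d}", fa.replicon, pa, pb,
                mate1_reverse_for(fa, orientation), read_len,
                replicon2=fb.replicon,
            ):
                out.write(a)
            n += 1
        for (fid, orientation), count in sorted((single_mate_requests or {}).items()):
            f = by_id[fid]
            check_len(f)
            for _ in range(count):
                p1, _ = positions(f)
                a1, _ = _make_pair(
                    header, f"pair{n:06d}", f.replicon, p1, p1,
                    mate1_reverse_for(f, orientation), read_len,
                )
                a1.flag |= 0x8  # mate unmapped
                a1.flag &= ~0x2
                out.write(a1)
                n += 1
        feats = [f for f in ann.features if f.length_bp >= read_len]
        for _ in range(n_imperfect_pairs):
            f = feats[int(rng.integers(len(feats)))]
            p1, p2 = positions(f)
            for a in _make_pair(
                header, f"pair{n:06d}", f.replicon, p1, p2, False, read_len,
                nm1=1, nm2=1,
            ):
                out.write(a)
            n += 1


def emit_sam_fixtures(
    config: SimulationConfig,
    ann: Annotation,
    table: "StrandedCountTable",
    outdir: str,
    read_len: int = 40,
) -> dict[str, str]:
    """One SAM per sample reproducing the table's counts (perfect pairs only).

    Intended for small desk-scale tables; the file holds one pair per
    counted transcript.
    """
    import os

    paths = {}
    for sid in table.sample_ids():
        col = table.counts[sid]
        requests = {
            (fid, orientation): int(v)
            for (fid, orientation), v in col.items()
            if v > 0
        }
        path = os.path.join(outdir, f"{sid}.sam")
        emit_sam_fixture(ann, requests, path, read_len=read_len,
                         seed=int(np.random.default_rng([config.seed, 4]).integers(2**31)))
        paths[sid] = path
    return paths

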