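"""Synthetic small-RNA study generator with full ground truth.

The generator emulates the design of a case/control miRNA-seq study of a
hemizygous deletion: a toy genome carrying miRNA hairpins (a configurable
fraction inside the deletion interval), per-miRNA expression levels drawn
log-normally, negative-binomial count noise across replicate libraries, a
dosage effect halving in-region miRNAs in case samples, and raw 50 nt reads
reconstructed from the counts with isomiR 5'/3' end offsets, sequencing
errors, 3' adapter ligation and non-miRNA background fragments.

Every read carries a provenance record, so the quantification rules can be
scored against truth, and with error/offset/background switched off the
pipeline must reproduce ``true_counts`` exactly.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mirdel import formats

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = str.maketrans("ACGTN", "TGCAN")

CATEGORIES = ["protein_coding", "lincRNA", "snoRNA", "tRNA", "rRNA", "intergenic"]
_CATEGORY_PROBS = [0.40, 0.15, 0.10, 0.10, 0.10, 0.15]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Hairpin:
    """A pre-miRNA: its sequence, mature sub-intervals and genomic locus.

    Coordinates are 1-based inclusive.  ``matures`` holds
    ``(mature_id, start, end)`` sub-intervals on the hairpin sequence;
    ``locus`` is ``(contig, start, end, strand)`` on the toy genome.
    """

    id: str
    sequence: str
    matures: tuple[tuple[str, int, int], ...]
    locus: tuple[str, int, int, str]

    def validate(self) -> None:
        L = len(self.sequence)
        if not set(self.sequence) <= set("ACGT"):
            raise ValueError(f"{self.id}: non-ACGT base in hairpin sequence")
        for mid, s, e in self.matures:
            if not (1 <= s <= e <= L):
                raise ValueError(f"{mid}: mature interval [{s},{e}] outside hairpin (len {L})")
            if not (18 <= e - s + 1 <= 25):
                raise ValueError(f"{mid}: mature length {e - s + 1} outside [18, 25]")


@dataclass
class ToyReference:
    """Toy genome, hairpin set and flat gene annotation."""

    genome: dict[str, str]
    hairpins: list[Hairpin]
    gene_features: list[tuple[str, int, int, str, str]]

    def mature_ids(self) -> list[str]:
        return [mid for hp in self.hairpins for mid, _, _ in hp.matures]

    def mature_loci(self) -> dict[str, tuple[str, int, int]]:
        """Genomic interval of each mature miRNA, derived from its hairpin."""
        loci: dict[str, tuple[str, int, int]] = {}
        for hp in self.hairpins:
            contig, hs, he, strand = hp.locus
            for mid, ms, me in hp.matures:
                if strand == "+":
                    loci[mid] = (contig, hs + ms - 1, hs + me - 1)
                else:
                    loci[mid] = (contig, he - me + 1, he - ms + 1)
        return loci

    def validate(self) -> None:
        ids = self.mature_ids()
        if len(ids) != len(set(ids)):
            raise ValueError("mature ids are not unique genome-wide")
        for hp in self.hairpins:
            hp.validate()
            contig, s, e, strand = hp.locus
            if contig not in self.genome:
                raise ValueError(f"{hp.id}: locus contig {contig!r} not in genome")
            if not (1 <= s <= e <= len(self.genome[contig])):
                raise ValueError(f"{hp.id}: locus [{s},{e}] outside {contig}")
            if e - s + 1 != len(hp.sequence):
                raise ValueError(f"{hp.id}: locus span != hairpin length")
            planted = self.genome[contig][s - 1 : e]
            expect = hp.sequence if strand == "+" else revcomp(hp.sequence)
            if planted != expect:
                raise ValueError(f"{hp.id}: genome sequence at locus differs from hairpin")


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic dataset.

    Defaults mirror the motivating study: 9 control vs 7 case libraries,
    single-end 50 nt reads, the NEBNext 3' adapter, ~7% adapterless reads,
    and a deletion interval halving in-region miRNA expression in cases.
    ``n_mirnas`` counts hairpins; by default each carries one mature miRNA
    and 20% of hairpins fall inside the deletion interval (5 of 25).
    """

    n_control: int = 9
    n_case: int = 7
    n_mirnas: int = 25
    contig_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr22": 30_000, "chr12": 30_000}
    )
    deletion_interval: tuple[str, int, int] = ("chr22", 8_001, 16_000)
    deletion_effect: float = 0.5
    extra_de: list[tuple[str, float]] = field(default_factory=list)
    mean_expression: tuple[float, float] = (math.log(400.0), 1.2)
    min_mean: float = 0.0
    dispersion: float = 0.03
    depth_log_sd: float = 0.15
    inregion_fraction: float = 0.2
    two_mature_fraction: float = 0.0
    isomir_offset_probs: dict[int, float] = field(
        default_factory=lambda: {-3: 0.005, -2: 0.025, -1: 0.12, 0: 0.70, 1: 0.12, 2: 0.025, 3: 0.005}
    )
    error_rate: float = 0.002
    background_fraction: float = 0.15
    adapter: str = ADAPTER
    adapterless_fraction: float = 0.07
    read_length: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.n_control < 2 or self.n_case < 2:
            raise ValueError("need at least 2 samples per group")
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas must be >= 1")
        if self.deletion_effect <= 0:
            raise ValueError("deletion_effect must be > 0")
        if self.dispersion < 0:
            raise ValueError("NB dispersion must be >= 0")
        for p in (
            self.error_rate,
            self.background_fraction,
            self.adapterless_fraction,
            self.inregion_fraction,
            self.two_mature_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.isomir_offset_probs.values()) - 1.0) > 1e-9:
            raise ValueError("isomir_offset_probs must sum to 1")
        if any(abs(k) > 3 for k in self.isomir_offset_probs):
            raise ValueError("isomiR offsets must lie in [-3, 3]")
        contig, s, e = self.deletion_interval
        if contig not in self.contig_lengths or not (1 <= s <= e <= self.contig_lengths[contig]):
            raise ValueError(f"deletion_interval {self.deletion_interval} outside any contig")
        if self.read_length < 15:
            raise ValueError("read_length shorter than the shortest retainable insert")

    @property
    def samples(self) -> list[str]:
        return [f"ctrl{i + 1:02d}" for i in range(self.n_control)] + [
            f"case{i + 1:02d}" for i in range(self.n_case)
        ]

    @property
    def groups(self) -> dict[str, str]:
        return {s: ("control" if s.startswith("ctrl") else "case") for s in self.samples}


@dataclass
class TruthTable:
    """Ground truth: counts, DE status and per-read provenance."""

    true_counts: pd.DataFrame  # mature_id x sample
    true_de: dict[str, float]  # mature_id -> case-vs-control fold (!= 1)
    provenance: pd.DataFrame | None = None  # one row per simulated read


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def _make_hairpin_template(rng: np.random.Generator, idx: int, two_mature: bool):
    """Draw hairpin length and mature sub-interval(s) with >=4 nt flanks."""
    # mature length 21-23 nt: the canonical ~22 nt, and even the shortest
    # -3/-3 isomiR insert (15 nt) still passes the 15-35 length filter
    L = int(rng.integers(70, 111))
    matures = []
    if two_mature:
        m5 = int(rng.integers(21, 24))
        m3 = int(rng.integers(21, 24))
        s5 = int(rng.integers(5, 9))
        e3 = L - int(rng.integers(5, 9))
        matures = [(f"miR-{idx}-5p", s5, s5 + m5 - 1), (f"miR-{idx}-3p", e3 - m3 + 1, e3)]
        if matures[1][1] - matures[0][2] < 8:  # keep arms well separated
            L += 8
            matures[1] = (matures[1][0], matures[1][1] + 8, matures[1][2] + 8)
    else:
        m = int(rng.integers(21, 24))
        s = int(rng.integers(5, L - m - 3))
        matures = [(f"miR-{idx}", s, s + m - 1)]
    return L, matures


def build_toy_reference(config: SimulationConfig) -> ToyReference:
    """Generate the toy genome, hairpins and gene annotation.

    Deterministic for a given seed.  Hairpin sequences are planted into the
    genome at their loci (honoring strand), so genome re-alignment of miRNA
    reads finds them where the annotation says they are.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genome = {name: bytearray(_random_seq(rng, L), "ascii") for name, L in config.contig_lengths.items()}

    n_hp = config.n_mirnas
    n_in = max(1, math.ceil(config.inregion_fraction * n_hp))
    templates = []
    for i in range(n_hp):
        two = bool(rng.random() < config.two_mature_fraction)
        templates.append(_make_hairpin_template(rng, i + 1, two))

    # Non-overlapping placement slots: inside the deletion interval for the
    # first n_in hairpins, anywhere outside it for the rest.
    spacing = max(L for L, _ in templates) + 50
    dc, ds, de = config.deletion_interval
    in_slots = [(dc, int(p)) for p in range(ds, de - spacing, spacing)]
    out_slots = []
    for contig, clen in config.contig_lengths.items():
        for p in range(100, clen - spacing, spacing):
            if contig == dc and not (p + spacing < ds or p > de):
                continue
            out_slots.append((contig, p))
    if n_in > len(in_slots) or n_hp - n_in > len(out_slots):
        raise ValueError("toy genome too small for requested number of hairpins")
    in_pick = [in_slots[i] for i in rng.permutation(len(in_slots))[:n_in]]
    out_pick = [out_slots[i] for i in rng.permutation(len(out_slots))[: n_hp - n_in]]

    hairpins = []
    for i, ((L, matures), (contig, start)) in enumerate(zip(templates, in_pick + out_pick)):
        seq = _random_seq(rng, L)
        strand = "+" if rng.random() < 0.5 else "-"
        planted = seq if strand == "+" else revcomp(seq)
        genome[contig][start - 1 : start - 1 + L] = planted.encode()
        hairpins.append(
            Hairpin(
                id=f"mir-{i + 1}",
                sequence=seq,
                matures=tuple(matures),
                locus=(contig, start, start + L - 1, strand),
            )
        )

    # Tile gene features into the space left free by hairpins.
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    for hp in hairpins:
        contig, s, e, _ = hp.locus
        occupied[contig].append((max(1, s - 20), e + 20))
    features: list[tuple[str, int, int, str, str]] = []
    for contig, clen in config.contig_lengths.items():
        cursor = 1
        for s, e in sorted(occupied[contig]) + [(clen + 1, clen + 1)]:
            while s - cursor >= 250:
                flen = int(rng.integers(200, min(801, s - cursor - 20)))
                cat = CATEGORIES[int(rng.choice(len(CATEGORIES), p=_CATEGORY_PROBS))]
                strand = "+" if rng.random() < 0.5 else "-"
                features.append((contig, cursor, cursor + flen - 1, strand, cat))
                cursor += flen + 20
            cursor = max(cursor, e + 1)

    ref = ToyReference(
        genome={c: bytes(b).decode() for c, b in genome.items()},
        hairpins=hairpins,
        gene_features=features,
    )
    ref.validate()
    return ref


def _inregion_matures(ref: ToyReference, interval: tuple[str, int, int]) -> set[str]:
    contig, lo, hi = interval
    out = set()
    for mid, (c, s, e) in ref.mature_loci().items():
        if c == contig and lo <= (s + e) / 2 <= hi:
            out.add(mid)
    return out


def simulate_count_matrix(
    means: np.ndarray,
    case_folds: np.ndarray,
    n_control: int,
    n_case: int,
    alpha: float,
    size_factors: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw an NB count matrix with mean ``s_j * mu_i * fold_ij``.

    ``case_folds`` multiplies means in case columns only.  ``alpha`` is the
    NB dispersion (variance = mu + alpha * mu^2); alpha = 0 gives Poisson.
    """
    if alpha < 0:
        raise ValueError("NB dispersion must be >= 0")
    n = n_control + n_case
    fold = np.ones((len(means), n))
    fold[:, n_control:] = case_folds[:, None]
    mu = means[:, None] * fold * size_factors[None, :]
    if alpha == 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu))


def simulate_counts(ref: ToyReference, config: SimulationConfig) -> TruthTable:
    """Draw the true mature-miRNA count matrix for all libraries."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    matures = ref.mature_ids()
    loc, scale = config.mean_expression
    means = np.maximum(np.exp(rng.normal(loc, scale, size=len(matures))), config.min_mean)
    size_factors = np.exp(rng.normal(0.0, config.depth_log_sd, size=len(config.samples)))

    inregion = _inregion_matures(ref, config.deletion_interval)
    folds = np.array(
        [config.deletion_effect if m in inregion else 1.0 for m in matures]
    )
    extra = dict(config.extra_de)
    for i, m in enumerate(matures):
        if m in extra:
            folds[i] *= extra[m]

    counts = simulate_count_matrix(
        means, folds, config.n_control, config.n_case, config.dispersion, size_factors, rng
    )
    true_counts = pd.DataFrame(counts, index=matures, columns=config.samples)
    true_de = {m: f for m, f in zip(matures, folds) if f != 1.0}
    return TruthTable(true_counts=true_counts, true_de=true_de)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = BASES[BASES != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def synthesize_reads(
    truth: TruthTable,
    ref: ToyReference,
    config: SimulationConfig,
    outdir: str | os.PathLike,
) -> dict[str, Path]:
    """Write one FASTQ per sample and attach per-read provenance to ``truth``.

    Each miRNA read is its mature sequence extended/trimmed by the sampled
    5'/3' offsets on the hairpin, substitution errors applied, the 3'
    adapter appended (except for ``adapterless_fraction`` of reads), and the
    result padded with 'A' / truncated to ``read_length``.  Background reads
    are genome fragments (15-35 nt, either strand) drawn from non-hairpin
    gene features.  Qualities are constant 'I'.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    offs = np.array(sorted(config.isomir_offset_probs))
    offp = np.array([config.isomir_offset_probs[o] for o in offs])
    hp_by_mature = {mid: (hp, ms, me) for hp in ref.hairpins for mid, ms, me in hp.matures}
    pad = "A" * config.read_length

    paths: dict[str, Path] = {}
    prov_rows: list[tuple] = []
    for j, sample in enumerate(config.samples):
        rng = np.random.default_rng([config.seed, 2, j])
        reads: list[tuple[str, str, str]] = []
        serial = 0

        def emit(insert: str, origin: str, off5: int, off3: int) -> None:
            nonlocal serial
            insert = _apply_errors(insert, config.error_rate, rng)
            if rng.random() < config.adapterless_fraction:
                seq = insert
            else:
                seq = insert + config.adapter
            seq = (seq + pad)[: config.read_length]
            rid = f"{sample}.{serial}"
            serial += 1
            reads.append((rid, seq, "I" * len(seq)))
            prov_rows.append((rid, sample, origin, off5, off3))

        n_mirna = 0
        for mid, count in truth.true_counts[sample].items():
            if count == 0:
                continue
            hp, ms, me = hp_by_mature[mid]
            o5 = rng.choice(offs, size=count, p=offp)
            o3 = rng.choice(offs, size=count, p=offp)
            for off5, off3 in zip(o5, o3):
                insert = hp.sequence[ms + int(off5) - 1 : me + int(off3)]
                emit(insert, f"mature:{mid}", int(off5), int(off3))
            n_mirna += int(count)

        bf = config.background_fraction
        n_bg = int(round(n_mirna * bf / (1.0 - bf))) if bf > 0 else 0
        if n_bg and not ref.gene_features:
            raise ValueError("background requested but reference has no gene features")
        for _ in range(n_bg):
            contig, fs, fe, _, cat = ref.gene_features[rng.integers(len(ref.gene_features))]
            flen = int(rng.integers(15, 36))
            start = int(rng.integers(fs, max(fs, fe - flen + 1) + 1))
            frag = ref.genome[contig][start - 1 : start - 1 + flen]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            emit(frag, f"background:{cat}", 0, 0)

        path = outdir / f"{sample}.fastq"
        formats.write_fastq(path, reads)
        paths[sample] = path

    truth.provenance = pd.DataFrame(
        prov_rows, columns=["read_id", "sample", "origin", "off5", "off3"]
    )
    truth.true_counts.rename_axis("mature_id").to_csv(outdir / "true_counts.tsv", sep="\t")
    truth.provenance.to_csv(outdir / "provenance.tsv", sep="\t", index=False)
    return paths


def write_reference(ref: ToyReference, outdir: str | os.PathLike) -> dict[str, Path]:
    """Write genome FASTA, hairpin FASTA and the GFF3 annotation."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_fa = outdir / "genome.fa"
    hairpin_fa = outdir / "hairpins.fa"
    gff = outdir / "annotation.gff3"
    formats.write_fasta(genome_fa, ref.genome.items())
    formats.write_fasta(hairpin_fa, [(hp.id, hp.sequence) for hp in ref.hairpins])
    rows = []
    for hp in ref.hairpins:
        contig, s, e, strand = hp.locus
        rows.append(
            dict(seqid=contig, type="miRNA_primary_transcript", start=s, end=e, strand=strand,
                 attributes={"ID": hp.id})
        )
        for mid, ms, me in hp.matures:
            rows.append(
                dict(seqid=hp.id, type="miRNA", start=ms, end=me, strand="+",
                     attributes={"ID": mid, "Derives_from": hp.id})
            )
    for contig, s, e, strand, cat in ref.gene_features:
        rows.append(
            dict(seqid=contig, type="gene_feature", start=s, end=e, strand=strand,
                 attributes={"category": cat})
        )
    formats.write_gff3(gff, rows)
    return {"genome": genome_fa, "hairpins": hairpin_fa, "annotation": gff}


def load_reference(genome_fa, hairpin_fa, gff) -> ToyReference:
    """Rebuild a :class:`ToyReference` from the files ``write_reference`` emits."""
    genome = formats.read_fasta(genome_fa)
    hairpin_seqs = formats.read_fasta(hairpin_fa)
    ann = formats.read_gff3(gff)
    hairpins = []
    for _, row in ann[ann["type"] == "miRNA_primary_transcript"].iterrows():
        hid = row["ID"]
        matures = ann[(ann["type"] == "miRNA") & (ann["seqid"] == hid)]
        hairpins.append(
            Hairpin(
                id=hid,
                sequence=hairpin_seqs[hid],
                matures=tuple(
                    (m["ID"], int(m["start"]), int(m["end"])) for _, m in matures.iterrows()
                ),
                locus=(row["seqid"], int(row["start"]), int(row["end"]), row["strand"]),
            )
        )
    feats = [
        (r["seqid"], int(r["start"]), int(r["end"]), r["strand"], r["category"])
        for _, r in ann[ann["type"] == "gene_feature"].iterrows()
    ]
    ref = ToyReference(genome=genome, hairpins=hairpins, gene_features=feats)
    ref.validate()
    return ref
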