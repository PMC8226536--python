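"""Synthetic ground-truth generators for every other module.

Every generator is a pure function of its configuration and seed: reruns
are byte-identical. The locus-set generator emulates the genomic situation
the assay-design problem arises from — a multi-exon parent gene whose
spliced cDNA has been copied back into the genome several times without
introns, at 4-13% divergence, sometimes truncated or with a broken reading
frame; optionally a diverged paralog that kept its introns and ORF.
Mutations are substitutions only by default so that realized identity is
1 - divergence up to binomial noise (an indel mode exists behind a flag).

Cohort and treatment generators produce replicate CT tables with planted
group effects on the dCT scale (an effect of -1.32 cycles corresponds to a
2^1.32 ~ 2.5-fold expression difference), digital-PCR partition counts from
the Poisson occupancy model, and capillary amplicon sizes for poly-T
genotyping with +/-1 bp sizing noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .seqio import GeneModel, GenomicInterval, SequenceRecord, reverse_complement

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass(frozen=True)
class PseudogeneSpec:
    """One planted cDNA copy."""

    name: str
    divergence: float
    truncate_bp: int = 0
    disrupt_orf: bool = False
    retain_introns: bool = False
    strand: str = "+"

    def __post_init__(self):
        if not (0.0 <= self.divergence <= 0.3):
            raise ValueError(f"divergence {self.divergence} outside [0, 0.3]")


@dataclass(frozen=True)
class LocusSetConfig:
    seed: int
    exon_lengths: Tuple[int, ...]
    intron_lengths: Tuple[int, ...]
    pseudogenes: Tuple[PseudogeneSpec, ...]
    flank: int = 300
    indel_rate: float = 0.0  # optional indel mode; off by default

    def __post_init__(self):
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need exactly one intron between consecutive exons")
        if len(self.intron_lengths) < 1:
            raise ValueError("parent gene must have at least one intron")


@dataclass
class LocusSet:
    """A generated genome with full ground truth."""

    genome: List[SequenceRecord]
    gene_model: GeneModel
    cdna: SequenceRecord
    cds: Tuple[int, int]  # 1-based inclusive CDS interval on the cDNA
    truth: pd.DataFrame
    config: LocusSetConfig

    def chrom(self, name: str) -> str:
        return {r.id: r for r in self.genome}[name].seq

    def planted_sequence(self, name: str) -> SequenceRecord:
        """Sense-strand sequence of a planted locus (its putative transcript)."""
        row = self.truth.set_index("name").loc[name]
        seq = self.chrom(row["chrom"])[int(row["start"]) - 1 : int(row["end"])]
        if row["strand"] == "-":
            seq = reverse_complement(seq)
        return SequenceRecord(name, seq)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _build_cdna(rng: np.random.Generator, total: int) -> Tuple[str, int, int]:
    """Random cDNA with a clean ORF spanning ~90% of its length."""
    utr5 = 30
    cds_codons = (total - utr5 - 30) // 3
    cds_len = cds_codons * 3
    body = "".join(rng.choice(_CODONS, size=cds_codons - 2))
    cds = "ATG" + body + "TAA"
    utr3 = total - utr5 - cds_len
    seq = _random_seq(rng, utr5) + cds + _random_seq(rng, utr3)
    return seq, utr5 + 1, utr5 + cds_len


def _mutate(rng: np.random.Generator, seq: str, divergence: float, indel_rate: float) -> str:
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < divergence
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    out = "".join(arr)
    if indel_rate > 0:
        pieces = []
        for ch in out:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            pieces.append(ch)
            if r > 1 - indel_rate / 2:
                pieces.append(str(rng.choice(_BASES)))  # insertion
        out = "".join(pieces)
    return out


def _repair_stops(rng: np.random.Generator, original: str, mutated: str, cds_start: int, cds_end: int) -> str:
    """Revert any substitution that created an in-frame stop in the CDS.

    Used for the paralog analogue: a functional diverged gene is under
    selection to keep its reading frame open.
    """
    arr = list(mutated)
    arr[cds_start - 1 : cds_start + 2] = original[cds_start - 1 : cds_start + 2]  # keep ATG
    for pos0 in range(cds_start - 1, cds_end - 3, 3):
        codon = "".join(arr[pos0 : pos0 + 3])
        if codon in _STOPS and original[pos0 : pos0 + 3] not in _STOPS:
            arr[pos0 : pos0 + 3] = original[pos0 : pos0 + 3]
    return "".join(arr)


def _break_orf(rng: np.random.Generator, copy: str, cds_start: int, cds_len: int) -> str:
    """Plant a premature stop ~25% into the reading frame."""
    codon_idx = max(1, cds_len // 3 // 4)
    pos0 = cds_start - 1 + codon_idx * 3
    if pos0 + 3 > len(copy):
        pos0 = max(0, len(copy) - 3)
    return copy[:pos0] + "TAA" + copy[pos0 + 3 :]


def generate_locus_set(config: LocusSetConfig) -> LocusSet:
    """Build a synthetic genome: parent gene with introns plus planted copies.

    Each pseudogene is the spliced parent cDNA mutated at the configured
    divergence, optionally truncated at its 3' end or reading-frame broken,
    inserted intronless at its own locus; a ``retain_introns`` copy keeps
    the full exon/intron structure (the diverged-paralog analogue). The
    truth table records coordinates, divergence and class for scoring.
    """
    rng = np.random.default_rng(config.seed)
    total = sum(config.exon_lengths)
    cdna_seq, cds_start, cds_end = _build_cdna(rng, total)

    # assemble the parent chromosome
    exon_seqs = []
    pos = 0
    for L in config.exon_lengths:
        exon_seqs.append(cdna_seq[pos : pos + L])
        pos += L
    intron_seqs = [_random_seq(rng, L) for L in config.intron_lengths]
    parent_parts = [_random_seq(rng, config.flank)]
    exon_intervals = []
    cursor = config.flank
    for i, es in enumerate(exon_seqs):
        exon_intervals.append(
            GenomicInterval("chr_parent", cursor + 1, cursor + len(es))
        )
        parent_parts.append(es)
        cursor += len(es)
        if i < len(intron_seqs):
            parent_parts.append(intron_seqs[i])
            cursor += len(intron_seqs[i])
    parent_parts.append(_random_seq(rng, config.flank))
    parent_chrom = "".join(parent_parts)
    model = GeneModel("parent", "chr_parent", "+", tuple(exon_intervals))
    gene_region = parent_chrom[config.flank : cursor]

    genome = [SequenceRecord("chr_parent", parent_chrom)]
    rows = [
        {
            "name": "parent",
            "chrom": "chr_parent",
            "start": config.flank + 1,
            "end": cursor,
            "strand": "+",
            "divergence": 0.0,
            "length": cursor - config.flank,
            "class": "parent",
            "intronless": False,
            "orf_disrupted": False,
        }
    ]
    cds_len = cds_end - cds_start + 1
    for spec in config.pseudogenes:
        if spec.retain_introns:
            # diverged but functional: mutate exons ORF-preservingly,
            # introns freely, and reassemble the full gene structure
            mut_cdna = _mutate(rng, cdna_seq, spec.divergence, config.indel_rate)
            mut_cdna = _repair_stops(rng, cdna_seq, mut_cdna, cds_start, cds_end)
            parts, p = [], 0
            for i, L in enumerate(config.exon_lengths):
                parts.append(mut_cdna[p : p + L])
                p += L
                if i < len(intron_seqs):
                    parts.append(_mutate(rng, intron_seqs[i], spec.divergence, config.indel_rate))
            copy = "".join(parts)
        else:
            copy = _mutate(rng, cdna_seq, spec.divergence, config.indel_rate)
        if spec.truncate_bp:
            if spec.truncate_bp >= len(copy):
                raise ValueError(f"{spec.name}: truncation removes the whole copy")
            copy = copy[: len(copy) - spec.truncate_bp]
        if spec.disrupt_orf and not spec.retain_introns:
            copy = _break_orf(rng, copy, cds_start, cds_len)
        planted = reverse_complement(copy) if spec.strand == "-" else copy
        chrom_name = f"chr_{spec.name}"
        chrom_seq = _random_seq(rng, config.flank) + planted + _random_seq(rng, config.flank)
        genome.append(SequenceRecord(chrom_name, chrom_seq))
        rows.append(
            {
                "name": spec.name,
                "chrom": chrom_name,
                "start": config.flank + 1,
                "end": config.flank + len(planted),
                "strand": spec.strand,
                "divergence": spec.divergence,
                "length": len(planted),
                "class": "paralog" if spec.retain_introns else "pseudogene",
                "intronless": not spec.retain_introns,
                "orf_disrupted": spec.disrupt_orf,
            }
        )
    truth = pd.DataFrame(rows)
    return LocusSet(
        genome=genome,
        gene_model=model,
        cdna=SequenceRecord("parent_cdna", cdna_seq),
        cds=(cds_start, cds_end),
        truth=truth,
        config=config,
    )


def default_locus_config(seed: int = 17, include_paralog: bool = True) -> LocusSetConfig:
    """The standard test bed: a 10-exon parent (1676-nt cDNA) plus five
    intronless copies whose divergences match the 4-13% identity band of a
    real processed-pseudogene family, and optionally an intron-retaining
    paralog analogue."""
    pseudos = [
        PseudogeneSpec("P1", 0.0430),
        PseudogeneSpec("P1b", 0.0445),
        PseudogeneSpec("P2", 0.0412, strand="-"),
        PseudogeneSpec("P3", 0.1274, truncate_bp=220, disrupt_orf=True),
        PseudogeneSpec("P4", 0.0459, truncate_bp=214, disrupt_orf=True),
    ]
    if include_paralog:
        pseudos.append(PseudogeneSpec("T40L", 0.08, retain_introns=True))
    return LocusSetConfig(
        seed=seed,
        exon_lengths=(120, 150, 140, 180, 160, 170, 150, 180, 200, 226),
        intron_lengths=(300, 250, 400, 350, 280, 500, 320, 260, 450),
        pseudogenes=tuple(pseudos),
    )


# ---------------------------------------------------------------------------
# cohort CT tables


@dataclass(frozen=True)
class CohortConfig:
    """Case/control RT-qPCR cohort with a planted dCT group effect."""

    seed: int
    n_case: int = 47
    n_control: int = 20
    effect_dct: float = -1.32  # added to case-group target CTs (cycles)
    replicate_sd: float = 0.15
    baseline_dct: float = 5.0
    reference_mean_ct: float = 20.0
    n_replicates: int = 3
    target_assay: str = "IVS9"
    reference_assay: str = "ACTB"
    genotype_freqs: Tuple[Tuple[str, float], ...] = (
        ("rs_e4", 0.25),
        ("rs_prom", 0.30),
        ("rs_int2", 0.28),
        ("rs_int6_polyT", 0.45),
        ("rs_int8", 0.40),
        ("rs_utr", 0.35),
    )

    def __post_init__(self):
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("group sizes must be >= 2")
        if self.replicate_sd < 0:
            raise ValueError("replicate SD cannot be negative")


def generate_ct_table(config: CohortConfig) -> pd.DataFrame:
    """Long-format CT table: one row per sample x assay, replicate columns.

    Reference CTs ~ Normal(reference mean, replicate SD); target CTs ~
    Normal(reference mean + baseline dCT + group effect, replicate SD).
    Genotype columns are Bernoulli carrier flags at the configured allele
    frequencies.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    groups = ["case"] * config.n_case + ["control"] * config.n_control
    for i, group in enumerate(groups):
        sample = f"s{i + 1:03d}"
        genos = {
            name: int(rng.random() < freq) for name, freq in config.genotype_freqs
        }
        mu_t = config.reference_mean_ct + config.baseline_dct + (
            config.effect_dct if group == "case" else 0.0
        )
        for assay, mu in ((config.target_assay, mu_t), (config.reference_assay, config.reference_mean_ct)):
            reps = rng.normal(mu, config.replicate_sd, size=config.n_replicates)
            row = {"sample": sample, "group": group, "assay": assay}
            row.update({f"rep{k + 1}": float(v) for k, v in enumerate(reps)})
            row.update(genos)
            rows.append(row)
    return pd.DataFrame(rows)


def cohort_delta_cts(table: pd.DataFrame, target: str, reference: str) -> pd.DataFrame:
    """Per-sample dCT from a generated (or equally shaped) CT table."""
    reps = [c for c in table.columns if c.startswith("rep")]
    mean_ct = table.set_index(["sample", "assay"])[reps].mean(axis=1).unstack("assay")
    groups = table.drop_duplicates("sample").set_index("sample")["group"]
    out = pd.DataFrame(
        {"delta_ct": mean_ct[target] - mean_ct[reference], "group": groups}
    )
    return out.reset_index()


# ---------------------------------------------------------------------------
# digital PCR partitions


def generate_dpcr_partitions(
    concentration_per_ul: float,
    partitions: int = 26_000,
    volume_ul: float = 0.00091,
    seed: int = 0,
) -> Tuple[int, int]:
    """Simulate partition counts: each partition is positive with
    probability 1 - exp(-c*v). Drawn as one Binomial(partitions, p) sample,
    which is distributionally identical to independent per-partition draws.
    Returns (positives, total)."""
    if concentration_per_ul < 0:
        raise ValueError("concentration cannot be negative")
    rng = np.random.default_rng(seed)
    p = 1.0 - math.exp(-concentration_per_ul * volume_ul)
    return int(rng.binomial(partitions, p)), partitions


# ---------------------------------------------------------------------------
# oxidative-stress (H2O2) treatment dataset


@dataclass(frozen=True)
class H2o2Effects:
    """Fold-change multipliers for treated vs untreated cells.

    Defaults sample per cell line uniformly inside the ranges the
    oxidative-stress phenotype is expected to span: transcription up
    1.2-1.5x, mitochondrial genome copies down to 20-60%, membrane
    potential down to 20-75%.
    """

    rna_range: Tuple[float, float] = (1.2, 1.5)
    mtdna_range: Tuple[float, float] = (0.2, 0.6)
    mmp_range: Tuple[float, float] = (0.2, 0.75)
    replicate_sd: float = 0.1  # CT noise, cycles
    intensity_sigma: float = 0.05  # lognormal noise on fluorescence

    def __post_init__(self):
        for lo, hi in (self.rna_range, self.mtdna_range, self.mmp_range):
            if lo <= 0 or hi < lo:
                raise ValueError("effect multiplier ranges must be positive and ordered")


CELL_LINES = ("HepG2", "U-118", "U-87", "LN-229")


def generate_h2o2_dataset(
    effects: Optional[H2o2Effects] = None,
    seed: int = 0,
    cell_lines: Sequence[str] = CELL_LINES,
    n_treatments: int = 3,
) -> Dict[str, pd.DataFrame]:
    """Treated/untreated CT tables (RNA vs ACTB, mitochondrial DNA vs a
    single-copy nuclear reference) and JC-1 red/green intensities, with the
    planted per-line multipliers in a truth table."""
    eff = effects or H2o2Effects()
    rng = np.random.default_rng(seed)
    ct_rows, jc1_rows, truth_rows = [], [], []
    for line in cell_lines:
        mult = {
            "rna": float(rng.uniform(*eff.rna_range)),
            "mtdna": float(rng.uniform(*eff.mtdna_range)),
            "mmp": float(rng.uniform(*eff.mmp_range)),
        }
        truth_rows.append({"cell_line": line, **mult})
        for trt in range(1, n_treatments + 1):
            for condition in ("treated", "untreated"):
                for assay, ref, key, base_dct in (
                    ("RNA", "ACTB", "rna", 6.0),
                    ("MtDNA", "HGB", "mtdna", -4.0),
                ):
                    shift = -math.log2(mult[key]) if condition == "treated" else 0.0
                    for name, mu in ((assay, 20.0 + base_dct + shift), (ref, 20.0)):
                        reps = rng.normal(mu, eff.replicate_sd, size=3)
                        ct_rows.append(
                            {
                                "cell_line": line,
                                "treatment": trt,
                                "condition": condition,
                                "assay": name,
                                **{f"rep{k + 1}": float(v) for k, v in enumerate(reps)},
                            }
                        )
                red_u, green_u = 1000.0, 800.0
                ratio_mult = mult["mmp"] if condition == "treated" else 1.0
                red = red_u * ratio_mult * float(rng.lognormal(0, eff.intensity_sigma))
                green = green_u * float(rng.lognormal(0, eff.intensity_sigma))
                jc1_rows.append(
                    {
                        "cell_line": line,
                        "treatment": trt,
                        "condition": condition,
                        "red": red,
                        "green": green,
                    }
                )
    return {
        "ct": pd.DataFrame(ct_rows),
        "jc1": pd.DataFrame(jc1_rows),
        "truth": pd.DataFrame(truth_rows),
    }


# ---------------------------------------------------------------------------
# poly-T genotyping cohort


def generate_polyt_cohort(
    genotypes: Sequence[Tuple[int, int]],
    seed: int = 0,
) -> pd.DataFrame:
    """Observed capillary amplicon sizes for poly-T genotypes.

    Each allele's observed size is 179 + tract length + uniform {-1, 0, +1}
    sizing noise. ``boundary_risk`` flags alleles whose tract length sits on
    a bin edge where that noise can cross into the neighbouring genotype
    class."""
    rng = np.random.default_rng(seed)
    rows = []
    risky = {19, 20, 29, 30}
    for i, pair in enumerate(genotypes):
        for allele_idx, length in enumerate(pair):
            if length < 0:
                raise ValueError("poly-T length cannot be negative")
            noise = int(rng.integers(-1, 2))
            rows.append(
                {
                    "sample": f"g{i + 1:03d}",
                    "allele": allele_idx + 1,
                    "true_polyt": length,
                    "observed_size": 179 + length + noise,
                    "boundary_risk": length in risky,
                }
            )
    return pd.DataFrame(rows)
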