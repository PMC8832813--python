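"""Synthetic genomes, gene models, bisulfite count tables, expression
counts and raw digestion reads with planted, recorded ground truth.

Everything is driven by a :class:`SimDesign` plus one integer seed and is
byte-deterministic.  CpG sites are planted as literal CG dinucleotides in
the generated sequence, with a higher density inside promoter windows to
mimic reduced-representation enrichment.  Replicate-level methylation
noise is beta-binomial with a configurable intra-class correlation;
expression counts are negative binomial with per-sample library-size
factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffmeth import MethCountTable
from .diffexpr import CountMatrix
from .regions import RegionLabel, RegionPartition, TranscriptModel

DEFAULT_BASELINES = {
    "P250": 0.22,
    "P1K": 0.57,
    "EXON": 0.76,
    "INTRON": 0.70,
    "P5K": 0.65,
    "FLANK": 0.70,
    "IGR": 0.75,
}


@dataclass
class SimDesign:
    """Parameters of one synthetic experiment."""

    n_chroms: int = 2
    chrom_length: int = 150_000
    n_genes: int = 20
    tissues: tuple[str, ...] = ("gonads", "liver")
    diets: tuple[str, ...] = ("L1", "L2", "L3")
    n_meth_reps: int = 3
    n_expr_reps: int = 6
    region_baselines: dict = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    bb_dispersion: float = 0.02
    mean_coverage: float = 30.0
    nb_dispersion: float = 0.05
    base_mean: float = 200.0
    tissue_effect_sd: float = 0.5
    libsize_range: tuple[float, float] = (0.7, 1.3)
    cpg_spacing: int = 150
    cpg_promoter_spacing: int = 40
    margin: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.diets) < 2:
            raise ValueError("need at least 2 diets (first is the control)")
        for k, v in self.region_baselines.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"baseline {k}={v} outside [0, 1]")
        for name in ("n_chroms", "chrom_length", "n_genes", "n_meth_reps",
                     "n_expr_reps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.bb_dispersion < 1.0:
            raise ValueError("bb_dispersion must be in [0, 1)")
        if self.mean_coverage <= 0 or self.nb_dispersion <= 0:
            raise ValueError("mean_coverage and nb_dispersion must be > 0")

    @property
    def control(self) -> str:
        return self.diets[0]


@dataclass
class TruthTable:
    """Planted ground truth of one simulation."""

    planted_dmcs: list = field(default_factory=list)  # (site, contrast, pp)
    planted_degs: list = field(default_factory=list)  # (gene, contrast, lfc)
    clip_events: list = field(default_factory=list)
    min_abs_effect: float = 30.0

    def validate(self, site_ids=None, gene_ids=None) -> None:
        if len(set(self.planted_dmcs)) != len(self.planted_dmcs):
            raise ValueError("duplicate planted DMC rows")
        if len(set(self.planted_degs)) != len(self.planted_degs):
            raise ValueError("duplicate planted DEG rows")
        for site, contrast, eff in self.planted_dmcs:
            if abs(eff) < self.min_abs_effect:
                raise ValueError(
                    f"planted effect {eff} pp at {site} below the "
                    f"configured minimum {self.min_abs_effect}"
                )
            if site_ids is not None and site not in site_ids:
                raise ValueError(f"planted DMC site {site} does not exist")
        if gene_ids is not None:
            for gene, contrast, lfc in self.planted_degs:
                if gene not in gene_ids:
                    raise ValueError(f"planted DEG gene {gene} does not exist")

    def dmc_sites(self, contrast: str) -> dict:
        return {
            s: e for s, c, e in self.planted_dmcs if c == contrast
        }

    def deg_genes(self, contrast: str) -> dict:
        return {g: l for g, c, l in self.planted_degs if c == contrast}


# ---------------------------------------------------------------------------
# Genome and gene models
# ---------------------------------------------------------------------------


def make_genome(
    design: SimDesign, max_tries: int = 200
) -> tuple[dict[str, str], dict[str, TranscriptModel]]:
    """Random chromosome sequences plus non-overlapping transcript models.

    Genes keep >= ``design.margin`` bp clearance from chromosome ends.
    Placement failure after bounded retries raises, naming the
    constraint.  CpG dinucleotides are planted throughout, denser inside
    the 1-kb promoter windows (see :func:`cpg_sites`).
    """
    rng = np.random.default_rng(design.seed)
    chroms = [f"chr{i + 1}" for i in range(design.n_chroms)]
    usable = design.chrom_length - 2 * design.margin
    if usable < 2000:
        raise ValueError(
            "chromosomes too short for the 10 kb end margins"
        )

    per_chrom = np.full(design.n_chroms, design.n_genes // design.n_chroms)
    per_chrom[: design.n_genes % design.n_chroms] += 1

    models: dict[str, TranscriptModel] = {}
    gene_no = 0
    for chrom, n_here in zip(chroms, per_chrom):
        spans: list[tuple[int, int]] = []
        for _ in range(int(n_here)):
            n_exons = int(rng.integers(1, 5))
            exon_lens = rng.integers(150, 801, size=n_exons)
            intron_lens = rng.integers(400, 2501, size=max(n_exons - 1, 0))
            length = int(exon_lens.sum() + intron_lens.sum())
            if design.chrom_length - design.margin - length + 1 <= design.margin:
                raise RuntimeError(
                    f"gene of length {length} cannot fit on a "
                    f"{design.chrom_length} bp chromosome inside the "
                    f"{design.margin} bp end margins"
                )
            placed = False
            for _ in range(max_tries):
                start = int(
                    rng.integers(
                        design.margin + 1,
                        design.chrom_length - design.margin - length + 2,
                    )
                )
                end = start + length - 1
                if all(end < s - 1 or start > e + 1 for s, e in spans):
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not place gene {gene_no + 1} on {chrom} without "
                    f"overlap inside the {design.margin} bp margins after "
                    f"{max_tries} tries"
                )
            spans.append((start, end))
            gene_no += 1
            gid = f"gene{gene_no:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            cursor = start
            for i, el in enumerate(exon_lens):
                exons.append((cursor, cursor + int(el) - 1))
                cursor += int(el)
                if i < len(intron_lens):
                    cursor += int(intron_lens[i])
            exons = tuple(exons)
            models[gid] = TranscriptModel(
                gene_id=gid,
                transcript_id=f"{gid}.t1",
                chrom=chrom,
                strand=strand,
                mrna_start=start,
                mrna_end=end,
                exons=exons,
            )

    genome = {}
    for chrom in chroms:
        seq = rng.choice(list("ACGT"), size=design.chrom_length)
        genome[chrom] = seq
    _plant_cpgs(design, rng, genome, models)
    return (
        {c: "".join(s) for c, s in genome.items()},
        models,
    )


def _promoter_windows(models):
    wins: dict[str, list[tuple[int, int]]] = {}
    for m in models.values():
        if m.strand == "+":
            wins.setdefault(m.chrom, []).append((m.tss - 1000, m.tss - 1))
        else:
            wins.setdefault(m.chrom, []).append((m.tss + 1, m.tss + 1000))
    return wins


def _plant_cpgs(design, rng, genome, models):
    """Overwrite CG dinucleotides at quasi-regular jittered positions."""
    wins = _promoter_windows(models)
    for chrom, seq in genome.items():
        length = len(seq)
        # scrub incidental CG dinucleotides so measured CpG sites are
        # exactly the planted ones (G -> T after a C creates no new CG)
        natural = (seq[:-1] == "C") & (seq[1:] == "G")
        seq[1:][natural] = "T"
        promoter = np.zeros(length + 1, dtype=bool)
        for s, e in wins.get(chrom, []):
            promoter[max(s, 1) : min(e, length) + 1] = True
        for spacing, in_promoter in (
            (design.cpg_spacing, False),
            (design.cpg_promoter_spacing, True),
        ):
            pos = np.arange(2, length - 2, spacing)
            pos = pos + rng.integers(0, max(spacing // 2, 1), size=pos.size)
            pos = pos[pos < length - 1]
            keep = promoter[pos] == in_promoter
            for p in pos[keep]:
                seq[p - 1] = "C"
                seq[p] = "G"


def cpg_sites(genome: dict[str, str]) -> list[tuple[str, int]]:
    """All CG dinucleotide positions (1-based position of the C)."""
    out = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        i = seq.find("CG")
        while i != -1:
            out.append((chrom, i + 1))
            i = seq.find("CG", i + 1)
    return out


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# RRBS counts
# ---------------------------------------------------------------------------


def simulate_rrbs(
    design: SimDesign,
    partition: RegionPartition,
    sites: list[tuple[str, int]],
    planted: list | None = None,
    tissue: str = "gonads",
    seed: int | None = None,
    min_abs_effect: float = 30.0,
) -> tuple[MethCountTable, TruthTable]:
    """Beta-binomial methylation counts around region-typical baselines.

    ``planted`` rows are (site_id, contrast, signed effect in percentage
    points); the effect shifts treatment samples of that contrast on the
    probability scale, clipped to [0.01, 0.99] with clip events recorded
    in the returned :class:`TruthTable`.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    site_ids = [f"{c}:{p}" for c, p in sites]
    labels = np.array(
        [partition.label_at(c, p).name for c, p in sites], dtype=object
    )
    baseline = np.array(
        [design.region_baselines[lab] for lab in labels], dtype=float
    )

    sample_rows = []
    for diet in design.diets:
        for r in range(design.n_meth_reps):
            sample_rows.append(
                {
                    "sample_id": f"{tissue}_{diet}_m{r + 1}",
                    "tissue": tissue,
                    "diet": diet,
                }
            )
    samples = pd.DataFrame(sample_rows)
    n_sites, n_samples = len(sites), len(samples)

    # per-site mean jitter around the region baseline (shared by samples)
    conc = 80.0
    site_mean = rng.beta(
        np.clip(baseline, 0.01, 0.99) * conc,
        np.clip(1 - baseline, 0.01, 0.99) * conc,
    )

    truth = TruthTable(min_abs_effect=min_abs_effect)
    effect = np.zeros((n_sites, n_samples))
    if planted:
        idx = {s: i for i, s in enumerate(site_ids)}
        diets_arr = samples["diet"].to_numpy()
        for site, contrast, eff in planted:
            if site not in idx:
                raise ValueError(f"planted site {site} not among sites")
            treatment = contrast.split(":")[0]
            effect[idx[site], diets_arr == treatment] += eff / 100.0
            truth.planted_dmcs.append((site, contrast, float(eff)))

    p = site_mean[:, None] + effect
    clipped = (p < 0.01) | (p > 0.99)
    if clipped.any() and planted:
        for i in sorted(set(np.nonzero(clipped.any(axis=1))[0])):
            truth.clip_events.append((site_ids[i], "probability clipped"))
        warnings.warn(
            f"{len(truth.clip_events)} site(s) had planted effects clipped "
            "to [0.01, 0.99]",
            stacklevel=2,
        )
    p = np.clip(p, 0.01, 0.99)

    rho = design.bb_dispersion
    if rho > 0:
        k = (1 - rho) / rho
        p_rep = rng.beta(p * k, (1 - p) * k)
    else:
        p_rep = p
    coverage = rng.poisson(design.mean_coverage, size=(n_sites, n_samples))
    methylated = rng.binomial(coverage, p_rep)

    table = MethCountTable(site_ids, samples, methylated, coverage)
    truth.validate(site_ids=set(site_ids))
    return table, truth


def choose_planted_dmcs(
    sites: list[tuple[str, int]],
    partition: RegionPartition,
    n: int,
    effect: float,
    contrasts: tuple[str, ...],
    seed: int = 0,
    region: str | None = None,
    baselines: dict | None = None,
) -> list:
    """Pick n sites (optionally restricted to one region label) and plant
    the same signed effect in every requested contrast.

    With ``baselines`` the sign is chosen by headroom (hyper below 0.5,
    hypo above) so effects are rarely clipped; otherwise signs are
    random.
    """
    rng = np.random.default_rng(seed)
    ids = np.array([f"{c}:{p}" for c, p in sites], dtype=object)
    labs = np.array(
        [partition.label_at(c, p).name for c, p in sites], dtype=object
    )
    if region is not None:
        ids, labs = ids[labs == region], labs[labs == region]
    if n > ids.size:
        raise ValueError(f"cannot plant {n} DMCs among {ids.size} sites")
    pick = rng.choice(ids.size, size=n, replace=False)
    if baselines is None:
        signs = rng.choice([-1.0, 1.0], size=n)
    else:
        signs = np.array(
            [1.0 if baselines[labs[i]] < 0.5 else -1.0 for i in pick]
        )
    out = []
    for i, sign in zip(pick, signs):
        for contrast in contrasts:
            out.append((str(ids[i]), contrast, float(sign * effect)))
    return out


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------


def simulate_rnaseq(
    design: SimDesign,
    models,
    planted: list | None = None,
    tissue: str = "gonads",
    seed: int | None = None,
) -> tuple[CountMatrix, TruthTable]:
    """Negative-binomial expression counts with planted log2 fold changes
    for treatment samples of the planted contrast."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    genes = sorted(models)
    sample_rows = []
    for diet in design.diets:
        for r in range(design.n_expr_reps):
            sample_rows.append(
                {
                    "sample_id": f"{tissue}_{diet}_e{r + 1}",
                    "tissue": tissue,
                    "diet": diet,
                }
            )
    samples = pd.DataFrame(sample_rows)
    n_genes, n_samples = len(genes), len(samples)

    base = rng.lognormal(np.log(design.base_mean), 1.0, size=n_genes)
    tissue_mult = (
        rng.lognormal(0.0, design.tissue_effect_sd, size=n_genes)
        if tissue != "gonads"
        else np.ones(n_genes)
    )
    lib = rng.uniform(*design.libsize_range, size=n_samples)

    truth = TruthTable()
    lfc_matrix = np.zeros((n_genes, n_samples))
    if planted:
        gidx = {g: i for i, g in enumerate(genes)}
        diets_arr = samples["diet"].to_numpy()
        for gene, contrast, lfc in planted:
            if gene not in gidx:
                raise ValueError(f"planted gene {gene} not among genes")
            treatment = contrast.split(":")[0]
            lfc_matrix[gidx[gene], diets_arr == treatment] += lfc
            truth.planted_degs.append((gene, contrast, float(lfc)))

    mu = base[:, None] * tissue_mult[:, None] * (2.0 ** lfc_matrix) * lib
    r = 1.0 / design.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    cm = CountMatrix(genes, samples, counts)
    truth.validate(gene_ids=set(genes))
    return cm, truth


# ---------------------------------------------------------------------------
# Raw digestion reads
# ---------------------------------------------------------------------------

DIGESTION_SIGNATURES = ("CGG", "TGG", "CGA", "TGA")
_NON_SIGNATURES = ("AGG", "ATT", "GCT", "TAC")


def simulate_fastq_digestion(
    path,
    n_reads: int,
    prop_valid: float = 0.97,
    read_length: int = 60,
    frac_long: float = 0.5,
    seed: int = 0,
) -> int:
    """Write a FASTQ where ``prop_valid`` of reads start with an enzyme
    digestion signature and ``frac_long`` exceed 50 bp (up to
    ``read_length``)."""
    if not 0.0 <= prop_valid <= 1.0:
        raise ValueError("prop_valid must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_valid = 0
    with open(path, "w") as fh:
        for i in range(n_reads):
            valid = rng.random() < prop_valid
            n_valid += int(valid)
            prefix = (
                DIGESTION_SIGNATURES[rng.integers(len(DIGESTION_SIGNATURES))]
                if valid
                else _NON_SIGNATURES[rng.integers(len(_NON_SIGNATURES))]
            )
            length = read_length if rng.random() < frac_long else min(
                40, read_length
            )
            tail = "".join(
                rng.choice(list("ACGT"), size=max(length - len(prefix), 0))
            )
            seq = (prefix + tail)[:length]
            fh.write(f"@read{i + 1}\n{seq}\n+\n{'I' * len(seq)}\n")
    return n_valid
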