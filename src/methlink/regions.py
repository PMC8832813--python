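"""Exclusive genomic partition and CpG site annotation.

The genome is split into exon, intron, three promoter tiers (P250, P1K,
P5K, measured upstream from the TSS), 10-kb mRNA flanks and the
intergenic remainder (IGR).  Overlaps are resolved by a fixed precedence:
exon > intron > P250 > P1K > P5K > flank > IGR.  Every position carries
exactly one label; all genes contributing the winning label are recorded.

Coordinates are 1-based inclusive throughout (GFF convention); the BED
export converts to 0-based half-open.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np


class RegionLabel(enum.IntEnum):
    """Region labels ordered by precedence (lower value wins)."""

    EXON = 1
    INTRON = 2
    P250 = 3
    P1K = 4
    P5K = 5
    FLANK = 6
    IGR = 7


EXON150 = "EXON150"

#: Default tier widths in bp.
DEFAULT_PARAMS = {
    "p250_len": 250,
    "p1k_len": 1000,
    "p5k_len": 5000,
    "flank_len": 10000,
    "exon150_len": 150,
}


@dataclass(frozen=True)
class TranscriptModel:
    """A single (isoform-selected) transcript of a gene.

    ``exons`` are 1-based inclusive, sorted, non-overlapping intervals
    contained in ``[mrna_start, mrna_end]``.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    mrna_start: int
    mrna_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.mrna_start > self.mrna_end or self.mrna_start < 1:
            raise ValueError(f"{self.gene_id}: bad mRNA span")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: transcript has no exons")
        prev_end = None
        for s, e in self.exons:
            if s > e or s < self.mrna_start or e > self.mrna_end:
                raise ValueError(
                    f"{self.gene_id}: exon ({s}, {e}) outside mRNA span "
                    f"[{self.mrna_start}, {self.mrna_end}]"
                )
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        """Strand-aware first transcribed base."""
        return self.mrna_start if self.strand == "+" else self.mrna_end

    @property
    def length(self) -> int:
        return self.mrna_end - self.mrna_start + 1

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out


@dataclass(frozen=True)
class SiteAnnotation:
    """Exclusive region assignment of one CpG site."""

    chrom: str
    pos: int
    label: RegionLabel
    gene_ids: tuple[str, ...]
    distance_to_tss: int | None
    sublabel: str | None = None

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}"

    @property
    def region_name(self) -> str:
        """Display name with the Exon150 split applied."""
        if self.label is RegionLabel.EXON and self.sublabel == EXON150:
            return "Exon150"
        return {
            RegionLabel.EXON: "Exon",
            RegionLabel.INTRON: "Intron",
            RegionLabel.P250: "P250",
            RegionLabel.P1K: "P1K",
            RegionLabel.P5K: "P5K",
            RegionLabel.FLANK: "Flanks",
            RegionLabel.IGR: "IGR",
        }[self.label]


def select_longest_isoform(
    transcripts: Iterable[TranscriptModel],
) -> dict[str, TranscriptModel]:
    """Keep one transcript per gene: maximal mRNA span, ties broken by
    lexicographically smallest transcript id."""
    best: dict[str, TranscriptModel] = {}
    for t in transcripts:
        cur = best.get(t.gene_id)
        if (
            cur is None
            or t.length > cur.length
            or (t.length == cur.length and t.transcript_id < cur.transcript_id)
        ):
            best[t.gene_id] = t
    return best


@dataclass
class RegionPartition:
    """Exhaustive, exclusive per-base label map with gene back-references."""

    chrom_sizes: dict[str, int]
    labels: dict[str, np.ndarray]
    # per chromosome: parallel arrays of (start, end, label value, gene id)
    intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]
    models: dict[str, TranscriptModel]
    params: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PARAMS))

    def label_at(self, chrom: str, pos: int) -> RegionLabel:
        return RegionLabel(int(self.labels[chrom][pos - 1]))

    def genes_at(self, chrom: str, pos: int) -> tuple[str, ...]:
        lab = int(self.labels[chrom][pos - 1])
        if lab == RegionLabel.IGR:
            return ()
        starts, ends, labs, genes = self.intervals[chrom]
        hit = (starts <= pos) & (ends >= pos) & (labs == lab)
        return tuple(sorted(set(genes[hit])))


def _tier_intervals(
    model: TranscriptModel, params: Mapping[str, int]
) -> list[tuple[int, int, RegionLabel]]:
    """All labeled intervals claimed by one transcript (unclipped)."""
    out: list[tuple[int, int, RegionLabel]] = []
    for s, e in model.exons:
        out.append((s, e, RegionLabel.EXON))
    for s, e in model.introns():
        out.append((s, e, RegionLabel.INTRON))
    tss = model.tss
    p250, p1k, p5k = params["p250_len"], params["p1k_len"], params["p5k_len"]
    fl = params["flank_len"]
    if model.strand == "+":
        out.append((tss - p250, tss - 1, RegionLabel.P250))
        out.append((tss - p1k, tss - p250 - 1, RegionLabel.P1K))
        out.append((tss - p5k, tss - p1k - 1, RegionLabel.P5K))
    else:
        out.append((tss + 1, tss + p250, RegionLabel.P250))
        out.append((tss + p250 + 1, tss + p1k, RegionLabel.P1K))
        out.append((tss + p1k + 1, tss + p5k, RegionLabel.P5K))
    out.append((model.mrna_start - fl, model.mrna_start - 1, RegionLabel.FLANK))
    out.append((model.mrna_end + 1, model.mrna_end + fl, RegionLabel.FLANK))
    return out


def build_partition(
    models: Mapping[str, TranscriptModel] | Iterable[TranscriptModel],
    chrom_sizes: Mapping[str, int],
    **params: int,
) -> RegionPartition:
    """Build the precedence-resolved partition for the whole genome.

    Promoter tiers and flanks are truncated at chromosome edges; a
    transcript whose mRNA span exceeds the chromosome raises.
    """
    p = dict(DEFAULT_PARAMS)
    p.update(params)
    if not isinstance(models, Mapping):
        models = {m.gene_id: m for m in models}

    labels: dict[str, np.ndarray] = {
        c: np.full(int(n), RegionLabel.IGR, dtype=np.int8)
        for c, n in chrom_sizes.items()
    }
    iv: dict[str, list[tuple[int, int, int, str]]] = {c: [] for c in chrom_sizes}

    for gid, m in sorted(models.items()):
        if m.chrom not in chrom_sizes:
            raise ValueError(f"gene {gid}: unknown chromosome {m.chrom!r}")
        size = int(chrom_sizes[m.chrom])
        if m.mrna_start < 1 or m.mrna_end > size:
            raise ValueError(
                f"gene {gid}: mRNA [{m.mrna_start}, {m.mrna_end}] outside "
                f"chromosome {m.chrom} (size {size})"
            )
        for s, e, lab in _tier_intervals(m, p):
            s, e = max(s, 1), min(e, size)
            if s > e:
                continue
            iv[m.chrom].append((s, e, int(lab), gid))
            arr = labels[m.chrom]
            seg = arr[s - 1 : e]
            np.minimum(seg, np.int8(lab), out=seg)

    intervals = {}
    for c, lst in iv.items():
        if lst:
            starts, ends, labs, genes = zip(*lst)
        else:
            starts = ends = labs = genes = ()
        intervals[c] = (
            np.asarray(starts, dtype=np.int64),
            np.asarray(ends, dtype=np.int64),
            np.asarray(labs, dtype=np.int8),
            np.asarray(genes, dtype=object),
        )
    return RegionPartition(
        chrom_sizes=dict(chrom_sizes),
        labels=labels,
        intervals=intervals,
        models=dict(models),
        params=p,
    )


def _signed_distance(model: TranscriptModel, pos: int) -> int:
    """Signed distance to the TSS (negative upstream of transcription)."""
    return pos - model.tss if model.strand == "+" else model.tss - pos


def assign_sites(
    sites: Sequence[tuple[str, int]],
    partition: RegionPartition,
) -> list[SiteAnnotation]:
    """Annotate each (chrom, pos) site with its exclusive region label,
    contributing genes, and strand-aware distance to the nearest labeled
    gene's TSS."""
    unknown = sorted({c for c, _ in sites if c not in partition.labels})
    if unknown:
        bad = [f"{c}:{p}" for c, p in sites if c in unknown]
        raise ValueError(f"sites on unknown chromosomes: {', '.join(bad[:10])}")

    out: list[SiteAnnotation] = []
    for chrom, pos in sites:
        label = partition.label_at(chrom, pos)
        if label is RegionLabel.IGR:
            out.append(SiteAnnotation(chrom, pos, label, (), None))
            continue
        genes = partition.genes_at(chrom, pos)
        dist = min(
            (_signed_distance(partition.models[g], pos) for g in genes),
            key=abs,
        )
        out.append(SiteAnnotation(chrom, pos, label, genes, dist))
    return out


def split_exon150(
    annotations: Iterable[SiteAnnotation], cutoff: int | None = None
) -> list[SiteAnnotation]:
    """Tag exon sites within [0, cutoff) bp downstream of the TSS as EXON150.

    The cut is half-open: distance ``cutoff`` itself stays plain exon.
    """
    out = []
    for a in annotations:
        if (
            a.label is RegionLabel.EXON
            and a.distance_to_tss is not None
            and 0 <= a.distance_to_tss < (cutoff or DEFAULT_PARAMS["exon150_len"])
        ):
            out.append(replace(a, sublabel=EXON150))
        else:
            out.append(a)
    return out


# ---------------------------------------------------------------------------
# GFF3 / BED interchange
# ---------------------------------------------------------------------------


def write_gff3(models: Mapping[str, TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(models):
            m = models[gid]
            tid = m.transcript_id
            fh.write(
                f"{m.chrom}\tmethlink\tgene\t{m.mrna_start}\t{m.mrna_end}\t.\t"
                f"{m.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{m.chrom}\tmethlink\tmRNA\t{m.mrna_start}\t{m.mrna_end}\t.\t"
                f"{m.strand}\t.\tID={tid};Parent={gid}\n"
            )
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.chrom}\tmethlink\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}\n"
                )


def read_gff3(
    path,
    gene_key: str = "Parent",
    keep_longest: bool = True,
) -> dict[str, TranscriptModel]:
    """Read transcript models from GFF3 via gffutils (in-memory db).

    Returns one model per gene after longest-isoform selection (unless
    ``keep_longest`` is False, in which case the transcript id keys the
    result).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    transcripts = []
    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get(gene_key, [mrna.id])
        exons = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="exon")
        )
        if not exons:
            exons = [(mrna.start, mrna.end)]
        transcripts.append(
            TranscriptModel(
                gene_id=parents[0],
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                mrna_start=mrna.start,
                mrna_end=mrna.end,
                exons=tuple(exons),
            )
        )
    if keep_longest:
        return select_longest_isoform(transcripts)
    return {t.transcript_id: t for t in transcripts}


def write_partition_bed(partition: RegionPartition, path) -> None:
    """Export the partition as BED (0-based half-open), one record per
    maximal run of constant (label, gene set)."""
    with open(path, "w") as fh:
        for chrom in sorted(partition.labels):
            arr = partition.labels[chrom]
            run_start = 0
            prev_key = (int(arr[0]), partition.genes_at(chrom, 1))
            for i in range(1, len(arr) + 1):
                key = (
                    (int(arr[i]), partition.genes_at(chrom, i + 1))
                    if i < len(arr)
                    else None
                )
                if key != prev_key:
                    lab, genes = prev_key
                    name = RegionLabel(lab).name
                    if genes:
                        name += ":" + "|".join(genes)
                    fh.write(f"{chrom}\t{run_start}\t{i}\t{name}\n")
                    run_start = i
                    prev_key = key
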