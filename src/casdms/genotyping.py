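"""Genotype classification of edited T0 plants from amplicon allele tables.

A diploid T0 plant is classified from its allele-frequency spectrum into one
of five classes: WT, monoallelic (one edited allele, one wild type),
biallelic_heterozygous (two distinct edits), biallelic_homozygous (the same
edit on both alleles), or chimeric (a somatic mosaic that fits none of the
clean diploid patterns). Thresholds are explicit, configurable defaults —
amplicon genotyping has no community-standard cutoffs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class Allele:
    """One amplicon allele: a descriptor (``WT``, ``del5``, ``ins2``, ``sub``)
    and its read-frequency share."""

    descriptor: str
    frequency: float
    sequence: str | None = None


@dataclass
class AlleleTable:
    """Per-plant, per-target allele spectrum; frequencies sum to 1 (±1%)."""

    plant_id: str
    target_id: str
    alleles: list[Allele]
    read_depth: int

    def __post_init__(self) -> None:
        total = sum(a.frequency for a in self.alleles)
        if self.alleles and not (0.99 <= total <= 1.01):
            raise ValueError(
                f"allele frequencies for {self.plant_id} sum to {total:.4f}, not 1"
            )
        if any(a.frequency < 0 for a in self.alleles):
            raise ValueError("allele frequencies must be non-negative")

    @property
    def wt_fraction(self) -> float:
        return sum(a.frequency for a in self.alleles if a.descriptor == "WT")


@dataclass(frozen=True)
class GenotypeThresholds:
    """Decision thresholds for :func:`classify_genotype` (all configurable)."""

    min_depth: int = 100
    major_allele: float = 0.35  # an allele this frequent is a "major" allele
    wt_call: float = 0.95  # WT fraction at or above this -> WT plant
    homozygous_allele: float = 0.90  # one mutant allele at/above this -> homozygous
    wt_absent: float = 0.05  # WT below this counts as absent (biallelic calls)
    mono_wt_low: float = 0.35  # WT window for a clean monoallelic call
    mono_wt_high: float = 0.65


@dataclass
class GenotypeCall:
    plant_id: str
    target_id: str
    genotype: str  # class name or "no_call"
    indel_frequency: float
    major_alleles: list[Allele] = field(default_factory=list)


def classify_genotype(
    table: AlleleTable, thresholds: GenotypeThresholds = GenotypeThresholds()
) -> GenotypeCall:
    """Classify one plant; a total function above the depth cutoff.

    Rules, applied in order on the WT fraction w and mutant alleles at or
    above the major-allele threshold: WT if w >= 0.95; homozygous if one
    mutant allele >= 0.90 and w < 0.05; heterozygous if two distinct mutant
    major alleles and w < 0.05; monoallelic if 0.35 <= w <= 0.65 with exactly
    one mutant major allele; chimeric otherwise.
    """
    t = thresholds
    w = table.wt_fraction
    indel_freq = 1.0 - w
    if table.read_depth < t.min_depth:
        return GenotypeCall(table.plant_id, table.target_id, "no_call", indel_freq)
    mutant_major = [
        a
        for a in table.alleles
        if a.descriptor != "WT" and a.frequency >= t.major_allele
    ]
    if w >= t.wt_call:
        genotype = "WT"
    elif any(a.frequency >= t.homozygous_allele for a in mutant_major) and w < t.wt_absent:
        genotype = "biallelic_homozygous"
    elif len(mutant_major) >= 2 and w < t.wt_absent:
        genotype = "biallelic_heterozygous"
    elif t.mono_wt_low <= w <= t.mono_wt_high and len(mutant_major) == 1:
        genotype = "monoallelic"
    else:
        genotype = "chimeric"
    return GenotypeCall(table.plant_id, table.target_id, genotype, indel_freq, mutant_major)


_DEL_RE = re.compile(r"^del(\d+)$")


def deletion_sizes(tables: Iterable[AlleleTable]) -> list[int]:
    """Deletion lengths (bp) over all mutant alleles with ``del<n>`` descriptors."""
    sizes = []
    for t in tables:
        for a in t.alleles:
            m = _DEL_RE.match(a.descriptor)
            if m:
                sizes.append(int(m.group(1)))
    return sizes


def summarize_targets(
    calls: Sequence[GenotypeCall], tables: Sequence[AlleleTable] | None = None
) -> pd.DataFrame:
    """Per-target editing summary over called plants.

    Percentages use all plants with a call (no_call excluded) as the
    denominator: % edited (any non-WT class), % biallelic (homozygous +
    heterozygous), homozygous rate, and the deletion-size range when allele
    tables are supplied — e.g. 12 plants of which 6 homozygous gives a 50%
    homozygous rate.
    """
    rows = []
    by_target: dict[str, list[GenotypeCall]] = {}
    for c in calls:
        by_target.setdefault(c.target_id, []).append(c)
    tables_by_target: dict[str, list[AlleleTable]] = {}
    for t in tables or []:
        tables_by_target.setdefault(t.target_id, []).append(t)
    for target, tc in sorted(by_target.items()):
        called = [c for c in tc if c.genotype != "no_call"]
        n = len(called)
        if n == 0:
            continue
        n_edited = sum(c.genotype != "WT" for c in called)
        n_bi = sum(
            c.genotype in ("biallelic_homozygous", "biallelic_heterozygous")
            for c in called
        )
        n_hom = sum(c.genotype == "biallelic_homozygous" for c in called)
        sizes = deletion_sizes(tables_by_target.get(target, []))
        rows.append(
            {
                "target_id": target,
                "n_plants": n,
                "pct_edited": 100.0 * n_edited / n,
                "pct_biallelic": 100.0 * n_bi / n,
                "pct_homozygous": 100.0 * n_hom / n,
                "deletion_min_bp": min(sizes) if sizes else np.nan,
                "deletion_max_bp": max(sizes) if sizes else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=[
        "target_id", "n_plants", "pct_edited", "pct_biallelic",
        "pct_homozygous", "deletion_min_bp", "deletion_max_bp",
    ])


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


def _indel_pattern(
    alignment: Align.Alignment, cut_site: int, window: int
) -> tuple[tuple[str, int, int], ...]:
    """Indels (kind, ref_position, length) within +/- window of the cut site."""
    events = []
    ref_blocks, read_blocks = alignment.aligned
    # gaps between consecutive aligned blocks are deletions/insertions
    for (r0, r1), (q0, q1), (nr0, _), (nq0, _) in zip(
        ref_blocks[:-1], read_blocks[:-1], ref_blocks[1:], read_blocks[1:]
    ):
        if nr0 > r1:  # deletion in read
            events.append(("del", int(r1), int(nr0 - r1)))
        if nq0 > q1:  # insertion in read
            events.append(("ins", int(r1), int(nq0 - q1)))
    return tuple(
        e for e in events if abs(e[1] - cut_site) <= window
    )


def call_alleles_from_reads(
    reads: Sequence[SeqRecord | str],
    reference_amplicon: str,
    cut_site: int | None = None,
    window: int = 20,
    min_depth: int = 1,
) -> AlleleTable | None:
    """Minimal amplicon allele caller for synthetic fixtures.

    Each read is globally aligned to the reference (match +1, mismatch -1,
    gap open -4, extend -1); alleles are keyed by their indel pattern within
    +/-``window`` bp of the cut site (default: amplicon midpoint). Reads with
    no indel in the window are WT (substitution-only reads count as WT at the
    indel level, descriptor ``sub`` is reserved for table-based inputs).
    Returns None when fewer than ``min_depth`` reads are provided.
    """
    if len(reads) < min_depth:
        return None
    if cut_site is None:
        cut_site = len(reference_amplicon) // 2
    aligner = _make_aligner()
    tallies: dict[tuple, int] = {}
    for rec in reads:
        seq = str(rec.seq) if isinstance(rec, SeqRecord) else str(rec)
        if seq == reference_amplicon:
            key: tuple = ()
        else:
            aln = aligner.align(reference_amplicon, seq)[0]
            key = _indel_pattern(aln, cut_site, window)
        tallies[key] = tallies.get(key, 0) + 1
    n = sum(tallies.values())
    alleles = []
    for key, count in sorted(tallies.items(), key=lambda kv: -kv[1]):
        if not key:
            desc = "WT"
        else:
            net = {"del": 0, "ins": 0}
            for kind, _, length in key:
                net[kind] += length
            if net["del"] and not net["ins"]:
                desc = f"del{net['del']}"
            elif net["ins"] and not net["del"]:
                desc = f"ins{net['ins']}"
            else:
                desc = f"del{net['del']}ins{net['ins']}"
        # distinct indel patterns with the same net descriptor stay distinct
        while any(a.descriptor == desc for a in alleles):
            desc += "'"
        alleles.append(Allele(desc, count / n))
    plant_id = "plant"
    return AlleleTable(plant_id=plant_id, target_id="target", alleles=alleles, read_depth=n)
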