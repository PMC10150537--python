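"""Variant calling for the one-codon-change saturation library.

Reads are compared codon-by-codon against the reference CDS (substitution-only
chemistry, so reads of a different length are rejected rather than aligned).
Accepted calls are tabulated into a :class:`CountTable`; rejected reads are
tallied with a reason so that accepted + rejected always equals input.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqRecord import SeqRecord

from .codons import (
    DNA_BASES,
    MISSENSE,
    NONSENSE,
    SYNONYMOUS,
    WT_ID,
    CodonVariant,
    ReferenceCDS,
)

# rejection reasons
MULTI_CODON = "multi_codon"
LENGTH_MISMATCH = "length_mismatch"
AMBIGUOUS_BASE = "ambiguous_base"


@dataclass(frozen=True)
class CallResult:
    """Outcome of calling one read: WT, a variant list, or a rejection."""

    status: str  # "wt" | "variant" | "rejected"
    variants: tuple[CodonVariant, ...] = ()
    reason: str | None = None

    @property
    def id(self) -> str | None:
        if self.status == "wt":
            return WT_ID
        if self.status == "variant":
            return "+".join(v.id for v in self.variants)
        return None


def call_codon_variants(
    read_seq: str, reference: ReferenceCDS, max_codon_changes: int = 1
) -> CallResult:
    """Call codon substitutions in a full-CDS read.

    Returns WT for an identical read, the differing codon(s) when at most
    ``max_codon_changes`` codons differ, and a rejection otherwise
    (``length_mismatch``, ``ambiguous_base`` or ``multi_codon``).
    """
    seq = read_seq.upper()
    bad = set(seq) - set(DNA_BASES) - {"N"}
    if bad:
        raise ValueError(f"read contains non-ACGTN characters: {sorted(bad)}")
    if "N" in seq:
        return CallResult("rejected", reason=AMBIGUOUS_BASE)
    if len(seq) != len(reference.nt_seq):
        return CallResult("rejected", reason=LENGTH_MISMATCH)
    variants = []
    for idx, wt in enumerate(reference.codons, start=1):
        obs = seq[(idx - 1) * 3 : idx * 3]
        if obs != wt:
            variants.append(CodonVariant(idx, wt, obs))
    if not variants:
        return CallResult("wt")
    if len(variants) > max_codon_changes:
        return CallResult("rejected", reason=MULTI_CODON)
    return CallResult("variant", variants=tuple(variants))


def quality_filter(record: SeqRecord, min_mean_q: float = 25.0) -> bool:
    """Mean-quality read filter on PHRED+33 scores; boundary is inclusive."""
    quals = record.letter_annotations.get("phred_quality")
    if quals is None or len(quals) != len(record.seq):
        raise ValueError(f"record {record.id!r} lacks per-base qualities")
    return float(np.mean(quals)) >= min_mean_q


@dataclass
class CountTable:
    """Variant counts per sample with variant metadata and rejection tallies.

    ``counts``: DataFrame indexed by variant id (codon- or aa-level, plus the
    special ``WT`` row), columns are sample labels, entries are non-negative
    integers. ``meta``: per-row codon_index / wt_aa / obs_aa / consequence.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    rejections: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample", "reason", "count"])
    )
    level: str = "codon"  # "codon" | "aa"

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def totals(self) -> pd.Series:
        """Per-sample totals (column sums over accepted calls)."""
        return self.counts.sum(axis=0)


def variant_meta(variants: Iterable[CodonVariant], level: str = "codon") -> pd.DataFrame:
    """Metadata frame (codon_index, wt_aa, obs_aa, consequence) for variant rows.

    Includes the WT row. At aa level, missense/nonsense rows collapse to
    ``aa_id``; synonymous rows keep codon resolution (they are distinct
    sequence entities whose aa label would collide with wild type).
    """
    rows: dict[str, dict] = {
        WT_ID: {"codon_index": 0, "wt_aa": "", "obs_aa": "", "consequence": "wt"}
    }
    for v in variants:
        key = v.id if (level == "codon" or v.consequence == SYNONYMOUS) else v.aa_id
        rows[key] = {
            "codon_index": v.codon_index,
            "wt_aa": v.wt_aa,
            "obs_aa": v.obs_aa,
            "consequence": v.consequence,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "variant_id"
    return df


_ID_RE = re.compile(r"^([A-Z*])(\d+)([A-Z*])(?:/([ACGT]{3}))?$")


def meta_from_ids(ids: Iterable[str]) -> pd.DataFrame:
    """Reconstruct variant metadata from canonical id strings.

    Ids look like ``A2D/GAT`` (codon level), ``A2D`` (aa level) or ``WT``;
    consequence is derived from the encoded amino acids. Used when count
    tables are read back from TSV, where only ids survive.
    """
    rows = {}
    for vid in ids:
        if vid == WT_ID:
            rows[vid] = {"codon_index": 0, "wt_aa": "", "obs_aa": "", "consequence": "wt"}
            continue
        m = _ID_RE.match(vid)
        if not m:
            rows[vid] = {"codon_index": 0, "wt_aa": "", "obs_aa": "", "consequence": "other"}
            continue
        wt_aa, idx, obs_aa = m.group(1), int(m.group(2)), m.group(3)
        if obs_aa == "*":
            consequence = NONSENSE
        elif obs_aa == wt_aa:
            consequence = SYNONYMOUS
        else:
            consequence = MISSENSE
        rows[vid] = {
            "codon_index": idx,
            "wt_aa": wt_aa,
            "obs_aa": obs_aa,
            "consequence": consequence,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "variant_id"
    return df


def tabulate(
    calls: Iterable[tuple[str, CallResult]],
    variants: Iterable[CodonVariant] | None = None,
) -> CountTable:
    """Tally a stream of (sample, call) pairs into a CountTable.

    Accepted calls increment their variant row; rejections are tallied
    separately by reason, so per-sample accepted + rejected = input reads.
    When ``variants`` is given, all library rows are present (zero-filled);
    otherwise rows are the observed ids.
    """
    acc: Counter = Counter()
    rej: Counter = Counter()
    seen: dict[str, CodonVariant] = {}
    samples: list[str] = []
    for sample, call in calls:
        if sample not in samples:
            samples.append(sample)
        if call.status == "rejected":
            rej[(sample, call.reason)] += 1
        else:
            acc[(call.id, sample)] += 1
            for v in call.variants:
                seen.setdefault(v.id, v)
    universe = list(variants) if variants is not None else list(seen.values())
    ids = [WT_ID] + [v.id for v in universe]
    counts = pd.DataFrame(0, index=pd.Index(ids, name="variant_id"), columns=samples, dtype=int)
    for (vid, sample), n in acc.items():
        if vid not in counts.index:  # multi-codon ids when max_codon_changes > 1
            counts.loc[vid] = 0
        counts.loc[vid, sample] += n
    meta = variant_meta(universe)
    meta = meta.reindex(counts.index).fillna(
        {"codon_index": 0, "wt_aa": "", "obs_aa": "", "consequence": "other"}
    )
    rejections = pd.DataFrame(
        [{"sample": s, "reason": r, "count": n} for (s, r), n in sorted(rej.items())],
        columns=["sample", "reason", "count"],
    )
    return CountTable(counts=counts, meta=meta, rejections=rejections)


def aggregate_to_aa(table: CountTable) -> CountTable:
    """Collapse codon-level counts to amino-acid resolution.

    Missense and nonsense rows encoding the same substitution are summed under
    the ``<wt_aa><index><obs_aa>`` id; synonymous rows and WT are kept at codon
    resolution. Per-sample totals are conserved.
    """
    if table.level != "codon":
        raise ValueError("input must be a codon-level table")
    meta = table.meta
    keys = []
    for vid, row in meta.iterrows():
        if row["consequence"] in (MISSENSE, NONSENSE):
            keys.append(f"{row['wt_aa']}{int(row['codon_index'])}{row['obs_aa']}")
        else:
            keys.append(vid)
    group = pd.Series(keys, index=meta.index)
    counts = table.counts.groupby(group.reindex(table.counts.index)).sum()
    new_meta = meta.copy()
    new_meta.index = group
    new_meta = new_meta[~new_meta.index.duplicated(keep="first")]
    new_meta = new_meta.reindex(counts.index)
    counts.index.name = "variant_id"
    new_meta.index.name = "variant_id"
    return CountTable(
        counts=counts, meta=new_meta, rejections=table.rejections.copy(), level="aa"
    )


def call_reads(
    reads: Iterable[tuple[str, SeqRecord]],
    reference: ReferenceCDS,
    min_mean_q: float = 25.0,
    max_codon_changes: int = 1,
) -> Iterator[tuple[str, CallResult]]:
    """Quality-filter and call (sample, read) pairs; low-quality reads are
    rejected with reason ``low_quality``."""
    for sample, rec in reads:
        if rec.letter_annotations.get("phred_quality") is not None and not quality_filter(
            rec, min_mean_q
        ):
            yield sample, CallResult("rejected", reason="low_quality")
            continue
        yield sample, call_codon_variants(str(rec.seq), reference, max_codon_changes)
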