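"""Phenotype (enrichment) scoring of selection-round count tables.

A variant's phenotype score is the natural log of its relative enrichment
between two sequenced selection rounds:

    s = ln[ ((c_post + a) / (N_post + aV)) / ((c_pre + a) / (N_pre + aV)) ]

with pseudocount a (default 0.5) over V library rows. Scores are centered per
replicate on the median of the synonymous variants — the built-in neutral
anchor set — so that synonymous scores cluster around 0 by construction, and
a variant is called positive only when its centered score exceeds 0 in every
replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import CountTable, aggregate_to_aa
from .codons import SYNONYMOUS

#: replicate -> (pre_sample, post_sample) column labels
Design = dict[int, tuple[str, str]]


def paired_design(
    replicates: tuple[int, ...] = (1, 2, 3),
    pre_round: int = 3,
    post_round: int = 4,
    fmt: str = "rep{rep}_round{rnd}",
) -> Design:
    """The default round-3 -> round-4 design over numbered replicates."""
    return {
        r: (fmt.format(rep=r, rnd=pre_round), fmt.format(rep=r, rnd=post_round))
        for r in replicates
    }


def frequencies(counts: pd.DataFrame, alpha: float = 0.5) -> pd.DataFrame:
    """Pseudocounted frequencies f(v) = (c(v)+a) / (N + aV) per column."""
    if alpha < 0:
        raise ValueError("pseudocount must be non-negative")
    totals = counts.sum(axis=0)
    if (totals == 0).any() and alpha == 0:
        empty = list(totals.index[totals == 0])
        raise ValueError(f"degenerate sample(s) with zero total counts: {empty}")
    V = counts.shape[0]
    return (counts + alpha) / (totals + alpha * V)


def raw_enrichment(c_pre, n_pre, c_post, n_post, alpha: float = 0.5, n_rows: int = 1):
    """Log relative enrichment of post- vs pre-round pseudocounted frequencies.

    Vectorized over ``c_pre``/``c_post``; ``n_rows`` is V, the number of
    library rows sharing the pseudocount mass.
    """
    f_pre = (np.asarray(c_pre, float) + alpha) / (n_pre + alpha * n_rows)
    f_post = (np.asarray(c_post, float) + alpha) / (n_post + alpha * n_rows)
    return np.log(f_post / f_pre)


def apply_count_filter(
    counts: pd.DataFrame, design: Design, min_count: int = 50
) -> pd.DataFrame:
    """Per-replicate count filter: a variant passes in a replicate iff its
    summed counts over that replicate's sequenced rounds reach ``min_count``
    (inclusive). Column ``all`` requires a pass in every replicate."""
    out = pd.DataFrame(index=counts.index)
    for rep, (pre, post) in design.items():
        out[rep] = (counts[pre] + counts[post]) >= min_count
    out["all"] = out[list(design)].all(axis=1)
    return out


def synonymous_center(
    scores: pd.Series, anchor_scores: pd.Series, min_anchors: int = 10
) -> tuple[pd.Series, float, bool]:
    """Center raw scores on the median of the synonymous anchors.

    Returns (centered scores, offset, centered-flag). With fewer than
    ``min_anchors`` anchors the scores are returned uncentered (offset 0,
    flag False) with a warning — the neutral anchor is unreliable.
    """
    if len(anchor_scores) < min_anchors:
        warnings.warn(
            f"only {len(anchor_scores)} synonymous anchors (< {min_anchors}); "
            "scores left uncentered",
            stacklevel=2,
        )
        return scores.copy(), 0.0, False
    offset = float(anchor_scores.median())
    return scores - offset, offset, True


def aggregate_replicates(z_scores) -> tuple[float, bool]:
    """Mean centered score and strict all-replicates positivity."""
    z = [float(v) for v in z_scores if v is not None and np.isfinite(v)]
    if not z:
        raise ValueError("no replicate scores available")
    return float(np.mean(z)), all(v > 0 for v in z)


@dataclass
class ScoreResult:
    """Scored screen: one row per variant with per-replicate raw and centered
    scores, the count-filter flags and the positivity call."""

    records: pd.DataFrame
    design: Design
    offsets: dict[int, float]
    centered: dict[int, bool]
    level: str

    def summary(self) -> dict:
        r = self.records
        passing = r[r["passes_count_filter"]]
        return {
            "n_variants": int(len(r)),
            "n_passing": int(len(passing)),
            "n_positive": int(passing["is_positive"].sum()),
            "n_synonymous_anchors": int(
                (passing["consequence"] == SYNONYMOUS).sum()
            ),
            "offsets": {str(k): v for k, v in self.offsets.items()},
        }


def score_screen(
    table: CountTable,
    design: Design | None = None,
    alpha: float = 0.5,
    min_count: int = 50,
    level: str = "aa",
    min_syn_anchors: int = 10,
) -> ScoreResult:
    """Score a screen count table end to end.

    Aggregates to amino-acid resolution by default (codon-level by
    ``level='codon'``), computes per-replicate log enrichment with
    pseudocount ``alpha``, applies the inclusive ``min_count`` filter on each
    replicate's round sum, centers each replicate on its passing synonymous
    median, and calls a variant positive iff it passes the filter and its
    centered score is > 0 in all replicates.
    """
    if level == "aa" and table.level == "codon":
        table = aggregate_to_aa(table)
    if design is None:
        design = paired_design()
    counts, meta = table.counts, table.meta
    V = counts.shape[0]
    passes = apply_count_filter(counts, design, min_count)
    syn_mask = meta["consequence"] == SYNONYMOUS

    records = pd.DataFrame(index=counts.index)
    offsets: dict[int, float] = {}
    centered_flags: dict[int, bool] = {}
    z_cols = []
    for rep, (pre, post) in design.items():
        s = pd.Series(
            raw_enrichment(
                counts[pre], counts[pre].sum(), counts[post], counts[post].sum(),
                alpha=alpha, n_rows=V,
            ),
            index=counts.index,
        )
        anchors = s[syn_mask & passes[rep]]
        z, offset, was_centered = synonymous_center(s, anchors, min_syn_anchors)
        records[f"s_rep{rep}"] = s
        records[f"z_rep{rep}"] = z
        offsets[rep] = offset
        centered_flags[rep] = was_centered
        z_cols.append(f"z_rep{rep}")

    records["mean_score"] = records[z_cols].mean(axis=1)
    records["n_replicates_passing"] = passes[list(design)].sum(axis=1)
    records["passes_count_filter"] = passes["all"]
    records["is_positive"] = passes["all"] & (records[z_cols] > 0).all(axis=1)
    records["consequence"] = meta["consequence"]
    records["codon_index"] = meta["codon_index"].astype(int)
    records.index.name = "variant_id"
    return ScoreResult(
        records=records,
        design=design,
        offsets=offsets,
        centered=centered_flags,
        level=table.level,
    )


def call_hits(result: ScoreResult | pd.DataFrame) -> pd.DataFrame:
    """Positive, filter-passing records sorted by mean score, descending."""
    records = result.records if isinstance(result, ScoreResult) else result
    hits = records[records["passes_count_filter"] & records["is_positive"]]
    return hits.sort_values("mean_score", ascending=False)


def prioritize_interface(
    hits: pd.DataFrame, interface_residues: set[int]
) -> pd.DataFrame:
    """Restrict a hit table to residues on a user-supplied interface set
    (e.g. DNA/R-loop contact residues derived from a structure), preserving
    the score ordering."""
    if not interface_residues:
        warnings.warn("empty interface annotation: returning no hits", stacklevel=2)
        return hits.iloc[0:0]
    return hits[hits["codon_index"].isin(interface_residues)]
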