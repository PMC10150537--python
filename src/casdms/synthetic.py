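"""Ground-truth simulators for every pipeline stage.

Three experiment families are emulated:

* a bacterial survival screen over an NNK one-codon-change library — cell
  survival is proportional to nuclease activity (toxin-plasmid clearance), so
  a variant with survival weight ``w`` changes frequency by a factor ``w`` per
  selection round (deterministic expectation update), and sequencing adds one
  multinomial draw per sample;
* Spec-seq / SEAM-seq fractionation of a mismatch library under a known
  additive position x base mismatch-penalty matrix (kT units), with logistic
  (Fermi) binding occupancy and exponential cleavage survival;
* diploid T0-plant allele mixtures for the genotype classifier.

All randomness flows through ``numpy.random.Generator``; fixed seeds give
bit-reproducible outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import CountTable, variant_meta
from .codons import (
    MISSENSE,
    NONSENSE,
    WT_ID,
    CodonVariant,
    ReferenceCDS,
    enumerate_nnk_variants,
    random_reference_cds,
)
from .genotyping import Allele, AlleleTable

DNA = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# survival screen
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectConfig:
    """Ground-truth effect-class composition for missense substitutions.

    ``effect_scale`` sets the beneficial weight (w = scale) and the
    deleterious weight (w = 1/scale); ``frac_null`` is the fraction of
    missense substitutions rendered inactive (w = 0, like nonsense).
    """

    frac_beneficial: float = 0.10
    frac_deleterious: float = 0.15
    frac_null: float = 0.05
    effect_scale: float = 2.0

    def __post_init__(self) -> None:
        fracs = (self.frac_beneficial, self.frac_deleterious, self.frac_null)
        if any(not (0.0 <= f <= 1.0) for f in fracs) or sum(fracs) > 1.0 + 1e-12:
            raise ValueError("class fractions must lie in [0,1] and sum to <= 1")
        if self.effect_scale <= 0:
            raise ValueError("effect_scale must be positive")


@dataclass
class EffectMap:
    """variant_id -> survival weight w (w=1 is wild-type-equivalent).

    Weights are assigned per amino-acid substitution, so every codon encoding
    the same missense change carries the same w and amino-acid-level
    aggregation has a single ground truth. ``aa_weights`` maps the aa-level id.
    """

    weights: pd.Series
    aa_weights: pd.Series

    def __post_init__(self) -> None:
        w = self.weights.to_numpy(float)
        if not np.all(np.isfinite(w)) or (w < 0).any():
            raise ValueError("weights must be finite and non-negative")


def assign_effects(
    variants: list[CodonVariant],
    config: EffectConfig = EffectConfig(),
    seed: int | np.random.Generator = 0,
) -> EffectMap:
    """Draw ground-truth survival weights for an NNK variant list.

    Missense amino-acid substitutions are permuted and split into beneficial /
    deleterious / null / neutral classes at the configured proportions;
    synonymous variants are forced to w=1 and nonsense to w=0.
    """
    rng = _as_rng(seed)
    aa_ids = sorted({v.aa_id for v in variants if v.consequence == MISSENSE})
    n = len(aa_ids)
    order = rng.permutation(n)
    n_ben = int(round(config.frac_beneficial * n))
    n_del = int(round(config.frac_deleterious * n))
    n_null = int(round(config.frac_null * n))
    aa_w = pd.Series(1.0, index=pd.Index(aa_ids, name="aa_id"))
    aa_w.iloc[order[:n_ben]] = config.effect_scale
    aa_w.iloc[order[n_ben : n_ben + n_del]] = 1.0 / config.effect_scale
    aa_w.iloc[order[n_ben + n_del : n_ben + n_del + n_null]] = 0.0
    weights = {WT_ID: 1.0}
    for v in variants:
        if v.consequence == NONSENSE:
            weights[v.id] = 0.0
        elif v.consequence == MISSENSE:
            weights[v.id] = float(aa_w[v.aa_id])
        else:
            weights[v.id] = 1.0
    w_series = pd.Series(weights, name="w")
    w_series.index.name = "variant_id"
    return EffectMap(weights=w_series, aa_weights=aa_w.rename("w"))


@dataclass
class SelectionTrajectory:
    """Per-round frequency tables; ``rounds[0]`` is the input library."""

    rounds: list[pd.Series]

    @property
    def n_rounds(self) -> int:
        return len(self.rounds) - 1


def simulate_selection(
    initial_freqs: pd.Series, effects: EffectMap, n_rounds: int
) -> SelectionTrajectory:
    """Deterministic expectation update: f'(v) = f(v) w(v) / sum_u f(u) w(u)."""
    f = initial_freqs.astype(float)
    if not math.isclose(float(f.sum()), 1.0, abs_tol=1e-9):
        raise ValueError("initial frequencies must sum to 1")
    w = effects.weights.reindex(f.index)
    if w.isna().any():
        missing = list(f.index[w.isna()])[:3]
        raise KeyError(f"effects missing for variants, e.g. {missing}")
    rounds = [f]
    for _ in range(n_rounds):
        fw = rounds[-1] * w
        total = float(fw.sum())
        if total <= 0.0:
            raise ValueError("degenerate selection: total survival weight is zero")
        rounds.append(fw / total)
    return SelectionTrajectory(rounds=rounds)


def simulate_counts(
    freq_table: pd.Series, depth: int, seed: int | np.random.Generator = 0
) -> pd.Series:
    """One multinomial sequencing draw of size ``depth`` over a frequency table."""
    if depth < 0:
        raise ValueError("depth must be a non-negative integer")
    rng = _as_rng(seed)
    p = freq_table.to_numpy(float)
    p = p / p.sum()
    draw = rng.multinomial(int(depth), p)
    return pd.Series(draw, index=freq_table.index, name="count")


def sample_name(replicate: int, round_: int) -> str:
    return f"rep{replicate}_round{round_}"


@dataclass
class ScreenSimulation:
    """A complete simulated screen with its ground truth attached."""

    reference: ReferenceCDS
    variants: list[CodonVariant]
    effects: EffectMap
    trajectory: SelectionTrajectory
    table: CountTable
    sequenced_rounds: tuple[int, ...]
    n_replicates: int
    depth: int


def simulate_screen(
    n_codons: int = 300,
    effect_config: EffectConfig = EffectConfig(),
    n_rounds: int = 4,
    sequenced_rounds: tuple[int, ...] = (3, 4),
    n_replicates: int = 3,
    depth: int = 1_000_000,
    bottleneck: int | None = None,
    seed: int = 0,
    reference: ReferenceCDS | None = None,
) -> ScreenSimulation:
    """End-to-end screen simulator: NNK library -> selection -> sequencing.

    The library starts uniform over all NNK variants plus one WT share.
    Replicates share the deterministic selection trajectory and differ only in
    their multinomial sequencing draws, unless ``bottleneck`` is set, in which
    case each replicate's library is resampled to that many cells between
    rounds (transformation-efficiency bottleneck; off by default).
    """
    root = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in root.spawn(3 + n_replicates)]
    if reference is None:
        reference = random_reference_cds(n_codons, seed=streams[0])
    variants = enumerate_nnk_variants(reference)
    effects = assign_effects(variants, effect_config, seed=streams[1])
    ids = [WT_ID] + [v.id for v in variants]
    f0 = pd.Series(1.0 / len(ids), index=pd.Index(ids, name="variant_id"))
    trajectory = simulate_selection(f0, effects, n_rounds)

    columns = {}
    for rep in range(1, n_replicates + 1):
        rng = streams[2 + rep]
        if bottleneck is None:
            rounds = trajectory.rounds
        else:
            w = effects.weights.reindex(f0.index)
            f = f0
            rounds = [f]
            for _ in range(n_rounds):
                fw = f * w
                fw = fw / fw.sum()
                cells = rng.multinomial(int(bottleneck), fw.to_numpy(float))
                f = pd.Series(cells / cells.sum(), index=f0.index)
                rounds.append(f)
        for t in sequenced_rounds:
            columns[sample_name(rep, t)] = simulate_counts(rounds[t], depth, rng)
    counts = pd.DataFrame(columns)
    counts.index.name = "variant_id"
    table = CountTable(counts=counts, meta=variant_meta(variants))
    return ScreenSimulation(
        reference=reference,
        variants=variants,
        effects=effects,
        trajectory=trajectory,
        table=table,
        sequenced_rounds=tuple(sequenced_rounds),
        n_replicates=n_replicates,
        depth=depth,
    )


def variant_sequence(reference: ReferenceCDS, variant: CodonVariant | None) -> str:
    """Full CDS sequence of a variant (None or WT -> the reference itself)."""
    if variant is None:
        return reference.nt_seq
    i = (variant.codon_index - 1) * 3
    return reference.nt_seq[:i] + variant.obs_codon + reference.nt_seq[i + 3 :]


def simulate_reads(
    reference: ReferenceCDS,
    freqs: pd.Series,
    variants: list[CodonVariant],
    n_reads: int,
    error_rate: float = 0.001,
    quality: int = 37,
    seed: int | np.random.Generator = 0,
) -> list[SeqRecord]:
    """Emit FASTQ-ready reads from a variant frequency table.

    Each read is the full variant CDS with uniform per-base substitution
    errors at ``error_rate`` and a flat PHRED quality.
    """
    rng = _as_rng(seed)
    by_id = {v.id: v for v in variants}
    counts = simulate_counts(freqs, n_reads, rng)
    records: list[SeqRecord] = []
    i = 0
    for vid, n in counts.items():
        if n == 0:
            continue
        base_seq = variant_sequence(reference, by_id.get(vid))
        arr = np.frombuffer(base_seq.encode(), dtype="S1")
        for _ in range(int(n)):
            seq = arr.copy()
            if error_rate > 0:
                hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
                for pos in hits:
                    choices = [b for b in b"ACGT" if bytes([b]) != seq[pos]]
                    seq[pos] = choices[rng.integers(3)]
            rec = SeqRecord(
                Seq(seq.tobytes().decode()), id=f"read_{i:07d}", description=""
            )
            rec.letter_annotations["phred_quality"] = [quality] * len(seq)
            records.append(rec)
            i += 1
    order = rng.permutation(len(records))
    return [records[j] for j in order]


# ---------------------------------------------------------------------------
# Spec-seq / SEAM-seq
# ---------------------------------------------------------------------------


@dataclass
class SpecTruth:
    """Ground-truth additive mismatch-penalty model (kT units).

    ``energy_matrix`` is positions (1-based) x bases A/C/G/T with an exact
    zero at the target base; ``cleavage_rate_scale`` is the perfect-match
    cleavage extent used by the SEAM-seq survival model.
    """

    target_seq: str
    energy_matrix: pd.DataFrame
    cleavage_rate_scale: float = 1.0

    def __post_init__(self) -> None:
        L = len(self.target_seq)
        if list(self.energy_matrix.index) != list(range(1, L + 1)):
            raise ValueError("energy matrix rows must be 1..len(target)")
        if list(self.energy_matrix.columns) != list("ACGT"):
            raise ValueError("energy matrix columns must be A,C,G,T")
        m = self.energy_matrix.to_numpy(float)
        if not np.all(np.isfinite(m)):
            raise ValueError("penalties must be finite")
        for i, b in enumerate(self.target_seq):
            if m[i, _BASE_INDEX[b]] != 0.0:
                raise ValueError(f"penalty at target base must be 0 (position {i + 1})")
        if self.cleavage_rate_scale <= 0:
            raise ValueError("cleavage_rate_scale must be positive")

    def ddG(self, seqs: list[str]) -> np.ndarray:
        """Additive binding penalty of each sequence vs the perfect match."""
        L = len(self.target_seq)
        m = self.energy_matrix.to_numpy(float)
        idx = np.array([[_BASE_INDEX[b] for b in s] for s in seqs])
        if idx.shape[1] != L:
            raise ValueError("library sequences must match the target length")
        return m[np.arange(L)[None, :], idx].sum(axis=1)


def random_spec_truth(
    target_seq: str,
    seed: int | np.random.Generator = 0,
    core_len: int = 18,
    core_range: tuple[float, float] = (0.25, 3.0),
    distal_range: tuple[float, float] = (0.0, 0.5),
    cleavage_rate_scale: float = 1.0,
) -> SpecTruth:
    """Random penalty matrix: strong penalties over the PAM-proximal core
    (positions 1..core_len), weak penalties beyond — mirroring the empirical
    pattern that the first ~18 bp of the guide mediate most specificity."""
    rng = _as_rng(seed)
    L = len(target_seq)
    m = np.zeros((L, 4))
    for i in range(L):
        lo, hi = core_range if i < core_len else distal_range
        m[i] = rng.uniform(lo, hi, size=4)
        m[i, _BASE_INDEX[target_seq[i]]] = 0.0
    mat = pd.DataFrame(m, index=range(1, L + 1), columns=list("ACGT"))
    return SpecTruth(target_seq, mat, cleavage_rate_scale)


@dataclass
class SpecSeqCounts:
    """Per-sequence counts in the four library fractions."""

    counts: pd.DataFrame  # index: sequence; columns subset of the fractions below

    FRACTIONS = ("bound", "unbound", "cleaved", "mock")

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def specseq_fraction_probabilities(
    truth: SpecTruth,
    library: list[str],
    mu: float = 0.0,
    input_freqs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Exact per-fraction sequence frequencies under the generative model.

    Binding follows logistic occupancy p_b = 1/(1+exp(ddG - mu)); the SEAM-seq
    surviving fraction follows exp(-k exp(-ddG)) with k = cleavage_rate_scale;
    the mock fraction is the unselected library.
    """
    f = (
        np.full(len(library), 1.0 / len(library))
        if input_freqs is None
        else np.asarray(input_freqs, float)
    )
    ddg = truth.ddG(library)
    p_b = 1.0 / (1.0 + np.exp(ddg - mu))
    survive = np.exp(-truth.cleavage_rate_scale * np.exp(-ddg))
    cols = {
        "bound": f * p_b,
        "unbound": f * (1.0 - p_b),
        "cleaved": f * survive,
        "mock": f,
    }
    out = pd.DataFrame(cols, index=pd.Index(library, name="sequence"))
    return out / out.sum(axis=0)


def simulate_specseq(
    truth: SpecTruth,
    library: list[str],
    depths: dict[str, int] | int = 1_000_000,
    mu: float = 0.0,
    seed: int | np.random.Generator = 0,
    analytic: bool = False,
) -> SpecSeqCounts:
    """Sequence the four fractions of a Spec-seq/SEAM-seq experiment.

    ``analytic=True`` returns exact expected (float) counts — the infinite
    depth limit used for noiseless round-trip checks.
    """
    rng = _as_rng(seed)
    if isinstance(depths, int):
        depths = {frac: depths for frac in SpecSeqCounts.FRACTIONS}
    probs = specseq_fraction_probabilities(truth, library, mu)
    cols = {}
    for frac, depth in depths.items():
        if frac not in probs.columns:
            raise KeyError(f"unknown fraction {frac!r}")
        p = probs[frac].to_numpy()
        cols[frac] = p * depth if analytic else rng.multinomial(int(depth), p)
    return SpecSeqCounts(counts=pd.DataFrame(cols, index=probs.index))


# ---------------------------------------------------------------------------
# T0-plant allele mixtures
# ---------------------------------------------------------------------------

GENOTYPE_CLASSES = (
    "WT",
    "monoallelic",
    "biallelic_heterozygous",
    "biallelic_homozygous",
    "chimeric",
)


@dataclass
class PlantSimulation:
    tables: list[AlleleTable]
    labels: list[str]  # ground-truth class per plant, aligned with tables


def _mutant_allele(rng: np.random.Generator, freq: float, taken: set[str]) -> Allele:
    # deletion sizes span the 3-14 bp range seen in edited T0 plants
    while True:
        size = int(rng.integers(3, 15))
        name = f"del{size}"
        if name not in taken:
            taken.add(name)
            return Allele(descriptor=name, frequency=freq)


def simulate_plant_alleles(
    n_plants: int = 120,
    profile: dict[str, float] | None = None,
    chimeric_noise: float = 0.0,
    target_id: str = "target1",
    depth: int = 2000,
    seed: int | np.random.Generator = 0,
) -> PlantSimulation:
    """Diploid T0 allele mixtures with known genotype labels.

    ``profile`` gives class proportions over the five genotype classes
    (default: uniform). ``chimeric_noise`` is the probability of spiking an
    additional low-frequency (2-8%) allele into a plant, emulating somatic
    mosaicism that can push borderline plants into the chimeric class.
    """
    rng = _as_rng(seed)
    if profile is None:
        profile = {c: 1.0 / len(GENOTYPE_CLASSES) for c in GENOTYPE_CLASSES}
    unknown = set(profile) - set(GENOTYPE_CLASSES)
    if unknown:
        raise ValueError(f"unknown genotype classes in profile: {sorted(unknown)}")
    classes = list(profile)
    p = np.array([profile[c] for c in classes], float)
    p = p / p.sum()
    labels = [classes[i] for i in rng.choice(len(classes), size=n_plants, p=p)]
    tables: list[AlleleTable] = []
    for j, label in enumerate(labels):
        taken: set[str] = set()
        if label == "WT":
            alleles = [Allele("WT", 1.0)]
        elif label == "monoallelic":
            w = float(rng.uniform(0.42, 0.58))
            alleles = [Allele("WT", w), _mutant_allele(rng, 1.0 - w, taken)]
        elif label == "biallelic_homozygous":
            m = float(rng.uniform(0.965, 0.995))
            alleles = [_mutant_allele(rng, m, taken), Allele("WT", 1.0 - m)]
        elif label == "biallelic_heterozygous":
            w = float(rng.uniform(0.0, 0.035))
            m1 = float(rng.uniform(0.44, 0.52)) * (1.0 - w)
            alleles = [
                _mutant_allele(rng, m1, taken),
                _mutant_allele(rng, 1.0 - w - m1, taken),
            ]
            if w > 0:
                alleles.append(Allele("WT", w))
        else:  # chimeric: several substantial alleles plus intermediate WT
            w = float(rng.uniform(0.10, 0.30))
            split = rng.dirichlet([1.0, 1.0, 1.0]) * (1.0 - w)
            split = np.clip(split, 0.06, None)
            split = split / split.sum() * (1.0 - w)
            alleles = [Allele("WT", w)] + [
                _mutant_allele(rng, float(fr), taken) for fr in split
            ]
        if chimeric_noise > 0 and rng.random() < chimeric_noise:
            extra = float(rng.uniform(0.02, 0.08))
            scale = 1.0 - extra
            alleles = [Allele(a.descriptor, a.frequency * scale) for a in alleles]
            alleles.append(_mutant_allele(rng, extra, taken))
        tables.append(
            AlleleTable(
                plant_id=f"plant_{j + 1:03d}",
                target_id=target_id,
                alleles=alleles,
                read_depth=depth,
            )
        )
    return PlantSimulation(tables=tables, labels=labels)
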