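"""Codon-level primitives: the standard genetic code, NNK degeneracy, and
single-codon variants of a reference coding sequence.

The saturation-mutagenesis library randomizes one codon at a time with NNK
degenerate primers (N = A/C/G/T at positions 1-2, K = G/T at position 3),
giving 32 codons per position that cover all 20 amino acids plus a single
stop codon (TAG). Variants are named in the field's residue convention,
e.g. ``G146R`` for a glycine-to-arginine change at residue 146, with the
encoding codon appended at codon resolution (``G146R/AGG``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Seq import Seq

DNA_BASES = ("A", "C", "G", "T")

#: The 32 NNK codons (N ∈ {A,C,G,T}, K ∈ {G,T}).
NNK_CODONS: tuple[str, ...] = tuple(
    a + b + c for a, b, c in itertools.product(DNA_BASES, DNA_BASES, ("G", "T"))
)

SYNONYMOUS = "synonymous"
MISSENSE = "missense"
NONSENSE = "nonsense"

#: Row id reserved for the unmutated reference in count tables.
WT_ID = "WT"


@lru_cache(maxsize=None)
def translate_codon(codon: str) -> str:
    """Translate a single codon with the standard genetic code ('*' = stop)."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in DNA_BASES for b in codon):
        raise ValueError(f"not a valid DNA codon: {codon!r}")
    return str(Seq(codon).translate())


def classify_substitution(wt_codon: str, obs_codon: str) -> str:
    """Consequence of a codon substitution: synonymous, missense or nonsense.

    Raises ``ValueError`` for identical codons — a substitution record must
    describe an actual change.
    """
    if wt_codon == obs_codon:
        raise ValueError("identical codons do not constitute a substitution")
    wt_aa, obs_aa = translate_codon(wt_codon), translate_codon(obs_codon)
    if obs_aa == "*":
        return NONSENSE
    if obs_aa == wt_aa:
        return SYNONYMOUS
    return MISSENSE


@dataclass(frozen=True)
class CodonVariant:
    """One codon substitution relative to the reference CDS.

    ``codon_index`` is 1-based, matching residue numbering (D156R etc.).
    """

    codon_index: int
    wt_codon: str
    obs_codon: str
    wt_aa: str = field(init=False)
    obs_aa: str = field(init=False)
    consequence: str = field(init=False)

    def __post_init__(self) -> None:
        if self.wt_codon == self.obs_codon:
            raise ValueError("variant must change the codon")
        object.__setattr__(self, "wt_aa", translate_codon(self.wt_codon))
        object.__setattr__(self, "obs_aa", translate_codon(self.obs_codon))
        object.__setattr__(
            self, "consequence", classify_substitution(self.wt_codon, self.obs_codon)
        )

    @property
    def id(self) -> str:
        """Canonical codon-level id, e.g. ``A2D/GAT``."""
        return f"{self.wt_aa}{self.codon_index}{self.obs_aa}/{self.obs_codon}"

    @property
    def aa_id(self) -> str:
        """Amino-acid-level id, e.g. ``A2D`` (collapses synonymous encodings)."""
        return f"{self.wt_aa}{self.codon_index}{self.obs_aa}"


@dataclass(frozen=True)
class ReferenceCDS:
    """A validated coding sequence: starts with ATG, length divisible by 3,
    no internal stop codons."""

    id: str
    nt_seq: str

    def __post_init__(self) -> None:
        seq = self.nt_seq.upper()
        object.__setattr__(self, "nt_seq", seq)
        if len(seq) == 0 or len(seq) % 3 != 0:
            raise ValueError("CDS length must be a positive multiple of 3")
        if any(b not in DNA_BASES for b in seq):
            raise ValueError("CDS contains non-ACGT characters")
        if not seq.startswith("ATG"):
            raise ValueError("CDS must begin with ATG")
        aa = str(Seq(seq).translate())
        if "*" in aa:
            raise ValueError("CDS contains an internal stop codon")

    @property
    def codons(self) -> list[str]:
        return [self.nt_seq[i : i + 3] for i in range(0, len(self.nt_seq), 3)]

    @property
    def n_codons(self) -> int:
        return len(self.nt_seq) // 3

    @property
    def aa_seq(self) -> str:
        return str(Seq(self.nt_seq).translate())


def enumerate_nnk_variants(reference: ReferenceCDS) -> list[CodonVariant]:
    """All single-codon NNK substitutions of the reference.

    At every codon position this emits the 32 NNK codons minus the wild-type
    codon when it is itself NNK-encodable (third base G or T) — the library
    design places exactly one codon change per clone.
    """
    variants: list[CodonVariant] = []
    for idx, wt in enumerate(reference.codons, start=1):
        for codon in NNK_CODONS:
            if codon != wt:
                variants.append(CodonVariant(idx, wt, codon))
    return variants


# Codons avoiding stops for random reference construction; start fixed to ATG.
_NONSTOP_CODONS = tuple(
    c
    for c in ("".join(p) for p in itertools.product(DNA_BASES, repeat=3))
    if translate_codon(c) != "*"
)


def random_reference_cds(
    n_codons: int, seed: int | np.random.Generator = 0, id: str = "synthetic_cds"
) -> ReferenceCDS:
    """A random stop-free CDS of ``n_codons`` codons beginning with ATG."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    body = rng.choice(len(_NONSTOP_CODONS), size=n_codons - 1)
    seq = "ATG" + "".join(_NONSTOP_CODONS[i] for i in body)
    return ReferenceCDS(id=id, nt_seq=seq)
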