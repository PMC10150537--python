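"""Spec-seq / SEAM-seq specificity analysis.

Spec-seq separates protein-bound from unbound library members; the log ratio
of bound/unbound counts, referenced to the perfect-match sequence, estimates
the relative binding free-energy penalty ddG (kT units). SEAM-seq sequences
the library surviving nuclease digestion against a mock treatment; depletion
from the surviving pool, referenced the same way, scores relative cleavage.
Per-sequence scores over a <=K-mismatch library are then regressed onto an
additive position x base mismatch-penalty matrix and presented as motif
logos. Positions are 1-based from the PAM-proximal end of the target window.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DNA_BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(DNA_BASES)}


# ---------------------------------------------------------------------------
# mismatch library
# ---------------------------------------------------------------------------


@dataclass
class MismatchLibrary:
    """Sequences within Hamming distance K of the target, with annotations."""

    target_seq: str
    members: pd.DataFrame  # index: sequence; column n_mismatches

    @property
    def sequences(self) -> list[str]:
        return list(self.members.index)

    def __len__(self) -> int:
        return len(self.members)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


def mismatch_class_size(length: int, k: int) -> int:
    """Number of sequences at exactly Hamming distance k: C(L,k) * 3^k."""
    return math.comb(length, k) * 3**k


def enumerate_mismatch_library(
    target: str,
    k_max: int = 4,
    mode: str = "exhaustive",
    quota_per_k: int | None = None,
    seed: int | np.random.Generator = 0,
) -> MismatchLibrary:
    """Build a <=``k_max``-mismatch library around a target sequence.

    Exhaustive mode enumerates all sum_{k<=K} C(L,k) 3^k sequences; sampled
    mode keeps the target plus ``quota_per_k`` uniform draws (without
    replacement) from each distance class, clipping over-large quotas with a
    warning.
    """
    target = target.upper()
    if not target or any(b not in DNA_BASES for b in target):
        raise ValueError("target must be a non-empty ACGT string")
    L = len(target)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seqs: list[str] = [target]
    n_mm: list[int] = [0]
    for k in range(1, k_max + 1):
        if mode == "exhaustive":
            for positions in itertools.combinations(range(L), k):
                alts = [tuple(b for b in DNA_BASES if b != target[p]) for p in positions]
                for combo in itertools.product(*alts):
                    s = list(target)
                    for p, b in zip(positions, combo):
                        s[p] = b
                    seqs.append("".join(s))
                    n_mm.append(k)
        elif mode == "sampled":
            if quota_per_k is None:
                raise ValueError("sampled mode requires quota_per_k")
            size = mismatch_class_size(L, k)
            quota = quota_per_k
            if quota > size:
                import warnings

                warnings.warn(
                    f"quota {quota} exceeds class size {size} at k={k}; clipped",
                    stacklevel=2,
                )
                quota = size
            chosen: set[str] = set()
            while len(chosen) < quota:
                positions = rng.choice(L, size=k, replace=False)
                s = list(target)
                for p in positions:
                    s[p] = DNA_BASES[
                        (_BASE_INDEX[target[p]] + 1 + rng.integers(3)) % 4
                    ]
                chosen.add("".join(s))
            for s in sorted(chosen):
                seqs.append(s)
                n_mm.append(k)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    members = pd.DataFrame(
        {"n_mismatches": n_mm}, index=pd.Index(seqs, name="sequence")
    )
    return MismatchLibrary(target_seq=target, members=members)


# ---------------------------------------------------------------------------
# per-sequence scores
# ---------------------------------------------------------------------------


def binding_energy(
    counts: pd.DataFrame, reference_seq: str, alpha: float = 0.5
) -> pd.Series:
    """Relative binding penalty from bound/unbound counts (kT units).

    ddG(s) = -ln[ ((b_s+a)/(u_s+a)) / ((b_ref+a)/(u_ref+a)) ]; the perfect
    match scores exactly 0, and with a=0 the score is invariant to uniform
    count scaling.
    """
    if reference_seq not in counts.index:
        raise KeyError("reference (perfect-match) sequence missing from counts")
    b = counts["bound"].astype(float) + alpha
    u = counts["unbound"].astype(float) + alpha
    logratio = np.log(b / u)
    ddg = -(logratio - logratio.loc[reference_seq])
    return ddg.rename("ddG")


def cleavage_score(
    counts: pd.DataFrame, reference_seq: str, alpha: float = 0.5
) -> pd.Series:
    """SEAM-seq depletion score (log units); higher = cleaved more efficiently.

    d(s) = ln[((m_s+a)/M) / ((c_s+a)/C)] referenced to the perfect match,
    where m/c are mock and cleaved-surviving counts. An uncleavable sequence
    is enriched in the surviving pool and scores negative.
    """
    if reference_seq not in counts.index:
        raise KeyError("reference (perfect-match) sequence missing from counts")
    M = float(counts["mock"].sum())
    C = float(counts["cleaved"].sum())
    if M <= 0:
        raise ValueError("mock totals must be positive")
    m = counts["mock"].astype(float) + alpha
    c = counts["cleaved"].astype(float) + alpha
    d = np.log((m / M) / (c / C))
    return (d - d.loc[reference_seq]).rename("depletion")


def harmonic_weights(
    counts: pd.DataFrame, fractions: tuple[str, str], alpha: float = 0.5
) -> pd.Series:
    """Inverse-variance proxy weights: harmonic mean of the two fraction
    counts (a log-ratio's sampling variance is ~ 1/n1 + 1/n2)."""
    a = counts[fractions[0]].astype(float) + alpha
    b = counts[fractions[1]].astype(float) + alpha
    return (2.0 / (1.0 / a + 1.0 / b)).rename("weight")


# ---------------------------------------------------------------------------
# additive energy-model regression
# ---------------------------------------------------------------------------


@dataclass
class EnergyModel:
    """Fitted position x base mismatch-penalty matrix (kT units).

    Exact zeros at target bases; entries with no supporting observation are
    NaN (missing, not zero). ``rmse``/``n_obs`` are fit diagnostics.
    """

    target_seq: str
    matrix: pd.DataFrame
    rmse: float = float("nan")
    n_obs: int = 0

    def __post_init__(self) -> None:
        L = len(self.target_seq)
        assert list(self.matrix.index) == list(range(1, L + 1))
        assert list(self.matrix.columns) == list(DNA_BASES)

    def ddG(self, seqs: list[str]) -> np.ndarray:
        m = self.matrix.to_numpy(float)
        L = len(self.target_seq)
        idx = np.array([[_BASE_INDEX[b] for b in s] for s in seqs])
        return m[np.arange(L)[None, :], idx].sum(axis=1)

    def mismatch_entries(self) -> pd.Series:
        """Flat series of the 3L free parameters (mismatch penalties)."""
        vals = {}
        for i, tb in enumerate(self.target_seq, start=1):
            for b in DNA_BASES:
                if b != tb:
                    vals[(i, b)] = self.matrix.at[i, b]
        return pd.Series(vals).rename("penalty")


class FitError(RuntimeError):
    pass


def fit_energy_model(
    scores: pd.Series,
    target_seq: str,
    weights: pd.Series | None = None,
) -> EnergyModel:
    """Weighted least-squares fit of additive single-position penalties.

    Model: score(s) = sum over mismatched positions i of eps[i][s_i]. The
    design must include the distance-0 anchor implicitly (its row is all
    zeros). Parameters with no observations are returned as NaN; a
    rank-deficient design over the observed parameters raises ``FitError``
    naming the unidentifiable entries.
    """
    target_seq = target_seq.upper()
    L = len(target_seq)
    seqs = list(scores.index)
    if any(len(s) != L for s in seqs):
        raise ValueError("all scored sequences must match the target length")
    params = [
        (i, b) for i in range(L) for b in DNA_BASES if b != target_seq[i]
    ]
    col_of = {p: j for j, p in enumerate(params)}
    X = np.zeros((len(seqs), len(params)))
    for r, s in enumerate(seqs):
        for i, (b, tb) in enumerate(zip(s, target_seq)):
            if b != tb:
                X[r, col_of[(i, b)]] = 1.0
    y = scores.to_numpy(float)
    w = (
        np.ones(len(seqs))
        if weights is None
        else weights.reindex(scores.index).to_numpy(float)
    )
    if (w < 0).any() or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and non-negative")
    observed = X.sum(axis=0) > 0
    Xo = X[:, observed]
    sw = np.sqrt(w)
    beta_o, _, rank, _ = np.linalg.lstsq(Xo * sw[:, None], y * sw, rcond=None)
    if rank < Xo.shape[1]:
        # identify unidentifiable columns via the null space
        _, sv, vt = np.linalg.svd(Xo * sw[:, None])
        null = vt[rank:]
        bad = np.where(np.abs(null).sum(axis=0) > 1e-8)[0]
        names = [params[j] for j, obs in enumerate(np.where(observed)[0]) if j in bad]
        raise FitError(f"rank-deficient design; unidentifiable parameters: {names}")
    beta = np.full(len(params), np.nan)
    beta[observed] = beta_o
    matrix = pd.DataFrame(
        0.0, index=range(1, L + 1), columns=list(DNA_BASES)
    )
    for (i, b), val in zip(params, beta):
        matrix.at[i + 1, b] = val
    resid = y - Xo @ beta_o
    rmse = float(np.sqrt(np.average(resid**2, weights=w)))
    return EnergyModel(target_seq=target_seq, matrix=matrix, rmse=rmse, n_obs=len(seqs))


def replicate_correlation(
    scores_rep1: pd.Series, scores_rep2: pd.Series
) -> tuple[float, int]:
    """Pearson r between replicate score sets over their shared sequences."""
    shared = scores_rep1.index.intersection(scores_rep2.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared sequences (< 3)")
    r = stats.pearsonr(scores_rep1.loc[shared], scores_rep2.loc[shared]).statistic
    return float(r), int(len(shared))


# ---------------------------------------------------------------------------
# logo / PWM export
# ---------------------------------------------------------------------------


@dataclass
class Pwm:
    probs: pd.DataFrame  # positions x ACGT, rows sum to 1
    missing_positions: list[int] = field(default_factory=list)

    def information(self) -> pd.Series:
        """Per-position information content in bits (2 - Shannon entropy)."""
        p = self.probs.to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.nansum(np.where(p > 0, p * np.log2(p), 0.0), axis=1)
        return pd.Series(2.0 - h, index=self.probs.index, name="bits")


def energy_to_pwm(model: EnergyModel) -> Pwm:
    """Boltzmann weights p[i][b] proportional to exp(-eps[i][b]) per position.

    Positions with missing (NaN) penalties are rendered uniform and listed in
    ``missing_positions``.
    """
    m = model.matrix.to_numpy(float)
    probs = np.exp(-m)
    missing = []
    for i in range(m.shape[0]):
        if np.isnan(m[i]).any():
            probs[i] = 0.25
            missing.append(i + 1)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return Pwm(
        probs=pd.DataFrame(probs, index=model.matrix.index, columns=list(DNA_BASES)),
        missing_positions=missing,
    )


def write_meme(pwm: Pwm, path, name: str = "motif") -> None:
    """Write the PWM in MEME minimal motif format."""
    p = pwm.probs
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        "A 0.25 C 0.25 G 0.25 T 0.25",
        "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {len(p)} nsites= 20 E= 0",
    ]
    for _, row in p.iterrows():
        lines.append(" ".join(f"{row[b]:.6f}" for b in DNA_BASES))
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


_LOGO_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}


def plot_logo(model: EnergyModel, path, title: str | None = None) -> None:
    """Render an information-content motif logo of the fitted model.

    Letter heights at each position are p[i][b] times the position's
    information content (bits); missing positions appear as uniform stacks.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    pwm = energy_to_pwm(model)
    info = pwm.information()
    fp = FontProperties(family="DejaVu Sans", weight="bold")
    fig, ax = plt.subplots(figsize=(max(4, 0.35 * len(pwm.probs)), 2.2))
    for x, (pos, row) in enumerate(pwm.probs.iterrows()):
        y0 = 0.0
        heights = sorted(
            ((row[b] * info[pos], b) for b in DNA_BASES), key=lambda t: t[0]
        )
        for h, b in heights:
            if h <= 1e-3:
                continue
            tp = TextPath((0, 0), b, size=1, prop=fp)
            bb = tp.get_extents()
            tf = (
                Affine2D()
                .translate(-bb.x0, -bb.y0)
                .scale(0.9 / bb.width, h / bb.height)
                .translate(x + 0.05, y0)
            )
            ax.add_patch(PathPatch(tf.transform_path(tp), color=_LOGO_COLORS[b], lw=0))
            y0 += h
    ax.set_xlim(0, len(pwm.probs))
    ax.set_ylim(0, 2.05)
    ax.set_xticks(np.arange(len(pwm.probs)) + 0.5)
    ax.set_xticklabels(pwm.probs.index, fontsize=7)
    ax.set_ylabel("bits")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
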