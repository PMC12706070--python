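"""Biochemical and positional featurization of activation domains.

Covers the sequence properties associated with transactivation: net charge
per residue, Kyte-Doolittle hydropathy, fraction of disorder-promoting
residues, and the blob-based patterning statistics kappa (mixing of positive
vs negative charges) and omega (mixing of aromatic/leucine hydrophobics
W,F,Y,L vs acidics D,E; lower = better mixed). Also maps each domain to its
position within its native protein, calls hits from per-target fold
changes, and computes hit/miss group statistics and predictor confusion
metrics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# Kyte & Doolittle hydropathy, shifted to the 0-9 convention downstream
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

POSITIVE = set("KR")  # histidine treated as neutral at physiological pH
NEGATIVE = set("DE")
HYDROPHOBIC_OMEGA = set("WFYL")
DISORDER_PROMOTING = set("TAGRDHQKSEP")


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"unknown residue letters: {sorted(bad)}")
    if not seq:
        raise ValueError("sequence must be non-empty")
    return seq


def composition_features(seq: str) -> tuple[float, float, float]:
    """(net charge per residue, mean hydropathy on [0, 9], disorder fraction).

    NCPR counts K/R as +1 and D/E as -1; hydropathy is the mean
    Kyte-Doolittle value rescaled linearly from [-4.5, 4.5] to [0, 9].
    """
    seq = _check_sequence(seq)
    n = len(seq)
    ncpr = (sum(c in POSITIVE for c in seq) - sum(c in NEGATIVE for c in seq)) / n
    hydropathy = float(np.mean([KYTE_DOOLITTLE[c] for c in seq]) + 4.5)
    f_disorder = sum(c in DISORDER_PROMOTING for c in seq) / n
    return float(ncpr), hydropathy, f_disorder


@dataclass(frozen=True)
class PatterningConfig:
    group_a: frozenset = frozenset(POSITIVE)
    group_b: frozenset = frozenset(NEGATIVE)
    blob_sizes: tuple[int, ...] = (5, 6)

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError("both residue groups must be non-empty")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("residue groups must be disjoint")


KAPPA_CONFIG = PatterningConfig(frozenset(POSITIVE), frozenset(NEGATIVE))
OMEGA_CONFIG = PatterningConfig(frozenset(HYDROPHOBIC_OMEGA), frozenset(NEGATIVE))


def _sigma(n_a: int, n_b: int, length: int) -> float:
    fa, fb = n_a / length, n_b / length
    if fa + fb == 0:
        return 0.0
    return (fa - fb) ** 2 / (fa + fb)


def _delta(ternary: np.ndarray, g: int, sigma_overall: float) -> float:
    """Mean squared deviation of window asymmetry from the global asymmetry."""
    is_a = (ternary == 1).astype(int)
    is_b = (ternary == -1).astype(int)
    ca = np.concatenate([[0], np.cumsum(is_a)])
    cb = np.concatenate([[0], np.cumsum(is_b)])
    n = len(ternary)
    devs = []
    for i in range(n - g + 1):
        na = ca[i + g] - ca[i]
        nb = cb[i + g] - cb[i]
        devs.append((_sigma(na, nb, g) - sigma_overall) ** 2)
    return float(np.mean(devs))


def _ternarize(seq: str, cfg: PatterningConfig) -> np.ndarray:
    return np.array(
        [1 if c in cfg.group_a else (-1 if c in cfg.group_b else 0) for c in seq],
        dtype=int,
    )


def _segregated(ternary: np.ndarray) -> np.ndarray:
    """Deterministic maximally segregated arrangement: A block, neutrals, B block."""
    n_a = int((ternary == 1).sum())
    n_b = int((ternary == -1).sum())
    n_0 = len(ternary) - n_a - n_b
    return np.array([1] * n_a + [0] * n_0 + [-1] * n_b, dtype=int)


def blob_patterning(
    seq: str,
    cfg: PatterningConfig,
    mc_normalizer_draws: int = 0,
    rng: np.random.Generator | None = None,
) -> float | None:
    """Degree of segregation of two residue groups along a sequence, in [0, 1].

    Per blob size g, the local asymmetry sigma = (f_A - f_B)^2 / (f_A + f_B)
    is computed over all length-g windows; delta(g) is the mean squared
    deviation of window sigma from the whole-sequence sigma. The score is
    the mean over blob sizes of delta(g) / delta_max(g), where delta_max
    comes from the maximally segregated permutation of the same composition
    (optionally cross-checked by Monte-Carlo maximization). 0 = perfectly
    mixed, 1 = fully segregated; None when either group is absent.
    """
    seq = _check_sequence(seq)
    if len(seq) < max(cfg.blob_sizes):
        raise ValueError("sequence shorter than the largest blob size")
    ternary = _ternarize(seq, cfg)
    n_a = int((ternary == 1).sum())
    n_b = int((ternary == -1).sum())
    if n_a == 0 or n_b == 0:
        return None
    sigma_overall = _sigma(n_a, n_b, len(ternary))
    seg = _segregated(ternary)

    ratios = []
    for g in cfg.blob_sizes:
        d = _delta(ternary, g, sigma_overall)
        d_max = _delta(seg, g, sigma_overall)
        if mc_normalizer_draws > 0:
            draws_rng = rng if rng is not None else np.random.default_rng(0)
            for _ in range(mc_normalizer_draws):
                perm = draws_rng.permutation(ternary)
                d_max = max(d_max, _delta(perm, g, sigma_overall))
        if d_max > 0:
            ratios.append(d / d_max)
    if not ratios:
        return None
    # neutral-containing sequences can segregate more strongly than the
    # block-wise normalizer arrangement; the score saturates at 1 there
    return float(min(np.mean(ratios), 1.0))


def kappa(seq: str, **kw) -> float | None:
    """Charge patterning: mixing of K/R against D/E."""
    return blob_patterning(seq, KAPPA_CONFIG, **kw)


def omega(seq: str, **kw) -> float | None:
    """Acidic-hydrophobic patterning: mixing of W/F/Y/L against D/E."""
    return blob_patterning(seq, OMEGA_CONFIG, **kw)


@dataclass(frozen=True)
class FeatureVector:
    ad_id: str
    ncpr: float
    hydropathy: float
    f_disorder: float
    kappa: float | None
    omega: float | None


def featurize(ad_id: str, seq: str) -> FeatureVector:
    ncpr, hydropathy, f_disorder = composition_features(seq)
    return FeatureVector(
        ad_id=ad_id,
        ncpr=ncpr,
        hydropathy=hydropathy,
        f_disorder=f_disorder,
        kappa=kappa(seq),
        omega=omega(seq),
    )


@dataclass(frozen=True)
class NativeContext:
    """Location of a domain within its native protein (1-based start N)."""

    N: int
    Ld: int
    Lp: int

    def __post_init__(self) -> None:
        if self.N < 1 or self.Ld < 1 or self.Lp < 1:
            raise ValueError("N, Ld and Lp must be positive")
        if self.N - 1 + self.Ld > self.Lp:
            raise ValueError("domain extends past the end of its protein")


def native_position_profile(
    ctx: NativeContext, n_sections: int = 20
) -> tuple[float, float, list[bool]]:
    """Normalized (start, end) of a domain and the protein sections it touches.

    start = (N-1)/Lp, end = (N-1+Ld)/Lp, so a domain starting at the first
    residue has start 0 and one running to the last residue has end 1. The
    protein is divided into n_sections equal sections; section i is flagged
    when the domain's span overlaps it with positive measure.
    """
    start = (ctx.N - 1) / ctx.Lp
    end = (ctx.N - 1 + ctx.Ld) / ctx.Lp
    flags = [
        start < i / n_sections and end > (i - 1) / n_sections
        for i in range(1, n_sections + 1)
    ]
    return start, end, flags


def section_frequencies(
    contexts: list[NativeContext], n_sections: int = 20
) -> np.ndarray:
    """Relative frequency with which domains touch each protein section."""
    if not contexts:
        raise ValueError("at least one native context is required")
    counts = np.zeros(n_sections)
    for ctx in contexts:
        _, _, flags = native_position_profile(ctx, n_sections)
        counts += np.asarray(flags, dtype=float)
    return counts / len(contexts)


def call_hits(
    fold_changes: dict[str, list[float]] | dict[str, np.ndarray],
    fold_threshold: float = 2.0,
    min_targets: int = 1,
) -> dict[str, bool]:
    """Hit = fold activation >= threshold on at least min_targets targets."""
    out = {}
    for ad_id, fc in fold_changes.items():
        fc = np.asarray(fc, dtype=float)
        if fc.size == 0:
            raise ValueError(f"{ad_id}: at least one fold change required")
        if (fc <= 0).any():
            raise ValueError(f"{ad_id}: fold changes must be positive")
        out[ad_id] = int((fc >= fold_threshold).sum()) >= min_targets
    return out


def compare_hits_misses(
    values, labels, welch: bool = False
) -> tuple[float, float]:
    """Unpaired two-sided t-test of a feature between hits and misses.

    Missing (None/NaN) feature values are excluded pairwise. Pooled-variance
    by default; welch=True uses unequal variances.
    """
    values = np.asarray(
        [np.nan if v is None else float(v) for v in values], dtype=float
    )
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    keep = np.isfinite(values)
    hits = values[keep & labels]
    misses = values[keep & ~labels]
    if len(hits) < 2 or len(misses) < 2:
        raise ValueError("each group needs at least two values")
    t, p = stats.ttest_ind(hits, misses, equal_var=not welch)
    return float(t), float(p)


def predictor_confusion(
    predicted_labels, hit_labels
) -> tuple[float | None, float | None]:
    """(sensitivity, precision) of a hit predictor; None when undefined."""
    pred = np.asarray(predicted_labels, dtype=bool)
    truth = np.asarray(hit_labels, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("label vectors must align")
    tp = int((pred & truth).sum())
    fn = int((~pred & truth).sum())
    fp = int((pred & ~truth).sum())
    sensitivity = tp / (tp + fn) if tp + fn > 0 else None
    precision = tp / (tp + fp) if tp + fp > 0 else None
    return sensitivity, precision


def enumerate_permutation_scores(
    seq: str, cfg: PatterningConfig
) -> dict[str, float]:
    """blob_patterning over every distinct permutation of a sequence.

    Brute-force oracle for small sequences (length <= ~10): verifies that
    the segregated arrangement attains the maximal score of 1.
    """
    seq = _check_sequence(seq)
    out: dict[str, float] = {}
    for perm in set(itertools.permutations(seq)):
        s = "".join(perm)
        val = blob_patterning(s, cfg)
        if val is not None:
            out[s] = val
    return out
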