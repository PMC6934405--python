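"""Consonant-confusion scoring and Miller–Nicely information transfer.

A confusion matrix ``N`` tallies stimulus–response counts from a
consonant-identification task.  The plug-in information transfer is

    T = sum_ij (n_ij / n) * log2( n * n_ij / (n_i. * n_.j) )   [bits],

the mutual information of the empirical joint distribution.  Because the
three phonetic features (voice, manner, place of articulation) differ in
number of categories and category priors, raw T values are not comparable
across features; *relative* information transfer divides T by the input
(stimulus) entropy, yielding a 0–100 % scale.

The consonant inventory is the 20-item set /b tʃ d f ɡ dʒ k l m n p r s
ʃ t θ v w j z/, each embedded in the vowel contexts /a i u/ (60
vowel-consonant-vowel tokens).  Of the 20 consonants 12 are voiced and 8
voiceless; manner has four categories (nasal, fricative, approximant,
plosive-initial) and place three (front, middle, back), so chance
identification of place is 1/3.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CONSONANTS",
    "VOWELS",
    "FEATURES",
    "FeatureMap",
    "ConfusionMatrix",
    "ITResult",
    "vcv_tokens",
    "load_feature_map",
    "percent_correct",
    "build_confusion",
    "collapse_to_feature",
    "input_entropy",
    "output_entropy",
    "information_transfer",
    "relative_it",
    "it_table",
]

CONSONANTS = (
    "b", "ch", "d", "f", "g", "jh", "k", "l", "m", "n",
    "p", "r", "s", "sh", "t", "th", "v", "w", "y", "z",
)
VOWELS = ("a", "i", "u")
FEATURES = ("voice", "manner", "place")

_FEATURE_CATEGORIES = {
    "voice": ("voiced", "voiceless"),
    "manner": ("nasal", "fricative", "approximant", "plosive"),
    "place": ("front", "middle", "back"),
}


def vcv_tokens() -> list[tuple[str, str]]:
    """All (consonant, vowel) VCV tokens: 20 consonants x 3 vowel contexts."""
    return [(c, v) for c in CONSONANTS for v in VOWELS]


@dataclass(frozen=True)
class FeatureMap:
    """Consonant -> (voice, manner, place) category table."""

    table: pd.DataFrame  # index: consonant; columns: voice, manner, place

    def __post_init__(self) -> None:
        tab = self.table
        if set(tab.index) != set(CONSONANTS):
            missing = set(CONSONANTS) - set(tab.index)
            extra = set(tab.index) - set(CONSONANTS)
            raise ValueError(f"feature map must cover the 20 consonants exactly "
                             f"(missing {sorted(missing)}, extra {sorted(extra)})")
        for feat in FEATURES:
            bad = set(tab[feat]) - set(_FEATURE_CATEGORIES[feat])
            if bad:
                raise ValueError(f"unknown {feat} categories: {sorted(bad)}")

    def category(self, consonant: str, feature: str) -> str:
        return str(self.table.at[consonant, feature])

    def categories(self, feature: str) -> tuple[str, ...]:
        """Category labels of a feature, in canonical order."""
        if feature not in _FEATURE_CATEGORIES:
            raise KeyError(f"unknown feature: {feature!r}")
        return _FEATURE_CATEGORIES[feature]

    def triple(self, consonant: str) -> tuple[str, str, str]:
        row = self.table.loc[consonant]
        return (row["voice"], row["manner"], row["place"])

    def consonants_matching(self, voice: str, manner: str, place: str) -> list[str]:
        tab = self.table
        mask = (tab["voice"] == voice) & (tab["manner"] == manner) & (tab["place"] == place)
        return list(tab.index[mask])

    def counts(self, feature: str) -> dict[str, int]:
        """Number of consonants per category of *feature*."""
        vc = self.table[feature].value_counts()
        return {cat: int(vc.get(cat, 0)) for cat in self.categories(feature)}


def load_feature_map(path=None) -> FeatureMap:
    """Load the consonant feature table (shipped default or a TSV of the same shape)."""
    if path is None:
        src = resources.files("tevoc").joinpath("data/feature_map.tsv")
        with resources.as_file(src) as p:
            tab = pd.read_csv(p, sep="\t", index_col="consonant")
    else:
        tab = pd.read_csv(path, sep="\t", index_col="consonant")
    return FeatureMap(tab[list(FEATURES)])


@dataclass(frozen=True)
class ConfusionMatrix:
    """Stimulus x response count matrix over a fixed label alphabet."""

    stim_labels: tuple[str, ...]
    resp_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.stim_labels), len(self.resp_labels)):
            raise ValueError("counts shape does not match label alphabets")
        if np.any(counts < 0):
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def stim_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def resp_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.stim_labels),
                            columns=list(self.resp_labels))


@dataclass(frozen=True)
class ITResult:
    it_bits: float
    input_entropy_bits: float
    relative_it: float  # percent


def percent_correct(trials: pd.DataFrame) -> float:
    """Percentage of trials whose response matches the stimulus."""
    if len(trials) == 0:
        raise ValueError("no trials")
    hits = (trials["response"] == trials["stimulus"]).sum()
    return 100.0 * float(hits) / len(trials)


def build_confusion(trials: pd.DataFrame, alphabet=CONSONANTS) -> ConfusionMatrix:
    """Tally a stimulus x response confusion matrix from a trial table.

    Vowel contexts, if present, are collapsed: only the ``stimulus`` and
    ``response`` columns are used.
    """
    alphabet = tuple(alphabet)
    index = {label: i for i, label in enumerate(alphabet)}
    counts = np.zeros((len(alphabet), len(alphabet)), dtype=np.int64)
    for col in ("stimulus", "response"):
        unknown = set(trials[col]) - set(alphabet)
        if unknown:
            raise ValueError(f"unknown {col} labels: {sorted(unknown)}")
    for s, r in zip(trials["stimulus"], trials["response"]):
        counts[index[s], index[r]] += 1
    return ConfusionMatrix(alphabet, alphabet, counts)


def collapse_to_feature(cm: ConfusionMatrix, fmap: FeatureMap, feature: str) -> ConfusionMatrix:
    """Sum confusion counts within the categories of one phonetic feature."""
    cats = fmap.categories(feature)
    cat_index = {c: i for i, c in enumerate(cats)}
    out = np.zeros((len(cats), len(cats)), dtype=cm.counts.dtype)
    for i, s in enumerate(cm.stim_labels):
        si = cat_index[fmap.category(s, feature)]
        for j, r in enumerate(cm.resp_labels):
            out[si, cat_index[fmap.category(r, feature)]] += cm.counts[i, j]
    return ConfusionMatrix(cats, cats, out)


def _entropy_bits(counts: np.ndarray) -> float:
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log2(p)))


def input_entropy(cm: ConfusionMatrix) -> float:
    """Entropy of the stimulus marginal distribution, in bits."""
    return _entropy_bits(cm.stim_marginals())


def output_entropy(cm: ConfusionMatrix) -> float:
    """Entropy of the response marginal distribution, in bits."""
    return _entropy_bits(cm.resp_marginals())


def information_transfer(cm: ConfusionMatrix, miller_madow: bool = False) -> float:
    """Plug-in Miller–Nicely information transfer in bits.

    ``T = sum_ij p_ij * log2(p_ij / (p_i * p_j))`` with ``0 log 0 := 0``.
    ``miller_madow=True`` adds the (K_joint - K_row - K_col + 1)/(2 n ln 2)
    small-sample bias correction (off by default; the classic analysis
    applies none).
    """
    n = cm.n_total
    if n <= 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(np.float64)
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = counts * n / (row * col)
        terms = np.where(counts > 0, counts / n * np.log2(np.where(counts > 0, ratio, 1.0)), 0.0)
    t = float(terms.sum())
    if miller_madow:
        k_joint = int((cm.counts > 0).sum())
        k_row = int((cm.stim_marginals() > 0).sum())
        k_col = int((cm.resp_marginals() > 0).sum())
        t += (k_joint - k_row - k_col + 1) / (2.0 * n * np.log(2.0))
    return max(t, 0.0)


def relative_it(cm: ConfusionMatrix, miller_madow: bool = False) -> ITResult:
    """Information transfer normalised by input entropy, as a percentage."""
    h_in = input_entropy(cm)
    if h_in <= 0:
        raise ValueError("input entropy is zero; relative IT undefined")
    t = information_transfer(cm, miller_madow=miller_madow)
    return ITResult(it_bits=t, input_entropy_bits=h_in,
                    relative_it=100.0 * min(t / h_in, 1.0))


def it_table(trials: pd.DataFrame, fmap: FeatureMap | None = None,
             by=("subject", "session")) -> pd.DataFrame:
    """Per-cell relative IT for each phonetic feature.

    Groups the trial table by *by* and, within each cell, builds the
    consonant confusion matrix, collapses it to each feature, and reports
    ``feature, it_bits, h_in, relative_it`` rows.
    """
    if fmap is None:
        fmap = load_feature_map()
    rows = []
    for keys, cell in trials.groupby(list(by), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        cm = build_confusion(cell)
        for feat in FEATURES:
            fcm = collapse_to_feature(cm, fmap, feat)
            res = relative_it(fcm)
            rows.append(dict(zip(by, keys)) | {
                "feature": feat,
                "it_bits": res.it_bits,
                "h_in": res.input_entropy_bits,
                "relative_it": res.relative_it,
            })
    return pd.DataFrame(rows)
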