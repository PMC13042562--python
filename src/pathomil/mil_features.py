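"""Multi-instance aggregation of patch predictions into patient feature vectors.

Each patient's bag of two-decimal patch probabilities and binary labels is
summarized twice over a fixed vocabulary — the 101 probability values
0.00..1.00 and the 2 label values — once as a min-max-normalized histogram
and once as an L2-normalized TF-IDF bag-of-words, then fused by concatenation

    Histo_prob (101) + Histo_pred (2) + Bow_prob (101) + Bow_pred (2) = 206

in that fixed order. The fixed vocabulary (rather than corpus-observed unique
values) guarantees the 206-dimensional representation on every cohort. IDF
weights are fitted on a training corpus and frozen for application to
validation patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import TfidfTransformer

from .fixtures import PatientBag

__all__ = [
    "ProbVocabulary",
    "FusedFeatureVector",
    "TfidfModel",
    "histo_features",
    "bow_tfidf",
    "fuse",
    "build_feature_table",
    "FEATURE_NAMES",
]

N_FEATURES = 206


@dataclass(frozen=True)
class ProbVocabulary:
    """Fixed term sets: 101 two-decimal probabilities and 2 binary labels."""

    prob_terms: tuple = tuple(round(i / 100, 2) for i in range(101))
    pred_terms: tuple = (0, 1)

    def __post_init__(self) -> None:
        if len(self.prob_terms) != 101 or len(self.pred_terms) != 2:
            raise ValueError("vocabulary must have 101 probability terms and 2 label terms")
        if list(self.prob_terms) != sorted(self.prob_terms) or list(self.pred_terms) != sorted(
            self.pred_terms
        ):
            raise ValueError("vocabulary terms must be strictly increasing")


DEFAULT_VOCAB = ProbVocabulary()

FEATURE_NAMES: list[str] = (
    [f"histo_prob_{t:.2f}" for t in DEFAULT_VOCAB.prob_terms]
    + [f"histo_pred_{t}" for t in DEFAULT_VOCAB.pred_terms]
    + [f"bow_prob_{t:.2f}" for t in DEFAULT_VOCAB.prob_terms]
    + [f"bow_pred_{t}" for t in DEFAULT_VOCAB.pred_terms]
)


@dataclass
class FusedFeatureVector:
    values: np.ndarray
    names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,) or len(self.names) != N_FEATURES:
            raise ValueError(f"fused feature vector must have length {N_FEATURES}")


def _counts(bag: PatientBag, vocab: ProbVocabulary) -> tuple[np.ndarray, np.ndarray]:
    prob_idx = np.rint(bag.probs * 100).astype(int)
    prob_counts = np.bincount(prob_idx, minlength=101).astype(float)
    pred_counts = np.bincount(bag.preds, minlength=2).astype(float)
    return prob_counts, pred_counts


def _minmax(counts: np.ndarray) -> np.ndarray:
    lo, hi = counts.min(), counts.max()
    if hi == lo:
        return np.zeros_like(counts)
    return (counts - lo) / (hi - lo)


def histo_features(
    bag: PatientBag, vocab: ProbVocabulary = DEFAULT_VOCAB
) -> tuple[np.ndarray, np.ndarray]:
    """Per-patient histogram blocks: term counts, min-max normalized per block.

    Normalization runs across the bins of one block within one patient;
    a block whose counts are all equal (max = min) maps to zeros.
    """
    prob_counts, pred_counts = _counts(bag, vocab)
    return _minmax(prob_counts), _minmax(pred_counts)


@dataclass
class TfidfModel:
    """Frozen IDF weights fitted on a training corpus, one per block."""

    idf_prob: np.ndarray
    idf_pred: np.ndarray
    n_documents: int

    def to_dict(self) -> dict:
        return {
            "idf_prob": self.idf_prob.tolist(),
            "idf_pred": self.idf_pred.tolist(),
            "n_documents": self.n_documents,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TfidfModel":
        return cls(np.asarray(d["idf_prob"]), np.asarray(d["idf_pred"]), d["n_documents"])


def _l2(rows: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(rows, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return rows / norms


def bow_tfidf(
    corpus: list[PatientBag],
    vocab: ProbVocabulary = DEFAULT_VOCAB,
    fitted: TfidfModel | None = None,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], TfidfModel]:
    """TF-IDF bag-of-words blocks per patient over the fixed vocabulary.

    tf(t, d) is the raw term count in bag d; idf(t) = ln((1+N)/(1+df(t))) + 1
    with N documents and df(t) the number of bags containing t; each block is
    L2-normalized per patient (a zero vector stays zero). Pass ``fitted`` to
    reapply training-corpus IDF weights unchanged to new patients.

    Returns the per-patient (bow_prob, bow_pred) blocks and the (possibly
    newly fitted) :class:`TfidfModel`.
    """
    if not corpus:
        raise ValueError("corpus must contain at least one patient bag")
    counts = [_counts(bag, vocab) for bag in corpus]
    tf_prob = np.stack([c[0] for c in counts])
    tf_pred = np.stack([c[1] for c in counts])
    if fitted is None:
        t_prob = TfidfTransformer(norm=None, smooth_idf=True, sublinear_tf=False).fit(tf_prob)
        t_pred = TfidfTransformer(norm=None, smooth_idf=True, sublinear_tf=False).fit(tf_pred)
        fitted = TfidfModel(t_prob.idf_, t_pred.idf_, len(corpus))
    w_prob = _l2(tf_prob * fitted.idf_prob)
    w_pred = _l2(tf_pred * fitted.idf_pred)
    return [(w_prob[i], w_pred[i]) for i in range(len(corpus))], fitted


def fuse(
    histo_prob: np.ndarray,
    histo_pred: np.ndarray,
    bow_prob: np.ndarray,
    bow_pred: np.ndarray,
) -> FusedFeatureVector:
    """Concatenate the four blocks in fixed order into the 206-vector."""
    blocks = [np.asarray(b, dtype=float) for b in (histo_prob, histo_pred, bow_prob, bow_pred)]
    expected = (101, 2, 101, 2)
    for b, e in zip(blocks, expected):
        if b.shape != (e,):
            raise ValueError(f"block lengths must be {expected}")
    return FusedFeatureVector(np.concatenate(blocks))


def build_feature_table(
    corpus: list[PatientBag],
    vocab: ProbVocabulary = DEFAULT_VOCAB,
    fitted: TfidfModel | None = None,
) -> tuple[pd.DataFrame, TfidfModel]:
    """One row of 206 named features per patient, indexed by patient_id.

    IDF is fitted on this corpus unless a frozen :class:`TfidfModel` is given.
    """
    ids = [bag.patient_id for bag in corpus]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient_id in corpus")
    bow, fitted = bow_tfidf(corpus, vocab, fitted)
    rows = []
    for bag, (bp, bl) in zip(corpus, bow):
        hp, hl = histo_features(bag, vocab)
        rows.append(fuse(hp, hl, bp, bl).values)
    table = pd.DataFrame(rows, index=pd.Index(ids, name="patient_id"), columns=FEATURE_NAMES)
    return table, fitted
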