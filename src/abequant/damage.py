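"""Sequence-based chromatin-accessibility damage scoring of candidate edits.

Every candidate off-target edit is evaluated by in-silico mutagenesis: a
predictor maps the reference sequence context and the edited context to
P(accessible) per track, and the damage score is

    damage = P(accessible | control) - P(accessible | edited)

A site is flagged when any track has P(accessible | control) > 0.2 and
damage > 0.1 for any evaluated edit.  The predictor is a declared interface
(input length, track list, batch scoring); the reference implementation is
a small 1-D convolutional network (motif filters, ReLU, global max pooling,
logistic head) trained on synthetic motif data with a seeded Adam loop, so
the whole stage is testable without external trained weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .core import GenomicInterval, ProtospacerSpec
from .offtargets import CandidateSite

DEFAULT_P_THRESHOLD = 0.2
DEFAULT_DAMAGE_THRESHOLD = 0.1

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class AccessibilityPrediction:
    """Per-track P(accessible) for one sequence."""

    per_track: dict[str, float]

    def __post_init__(self) -> None:
        for track, p in self.per_track.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"track {track!r} probability {p} outside [0, 1]")


@dataclass
class EditEvaluation:
    """One evaluated edit at a site."""

    description: str  # e.g. "A5", "A5+A6"
    positions: tuple[int, ...]
    p_edited: dict[str, float]
    damage: dict[str, float]


@dataclass
class DamageResult:
    site: CandidateSite
    p_control: dict[str, float]
    edits: list[EditEvaluation]
    max_damage: float
    flagged: bool


@runtime_checkable
class AccessibilityPredictor(Protocol):
    """Contract every accessibility model must satisfy."""

    input_length: int
    track_ids: tuple[str, ...]

    def predict_batch(self, sequences: Sequence[str]) -> np.ndarray:
        """(n_sequences, n_tracks) array of probabilities in [0, 1]."""
        ...


def one_hot(seq: str) -> np.ndarray:
    """(4, L) one-hot encoding; ambiguous bases encode as all-zero columns."""
    arr = np.zeros((4, len(seq)), dtype=np.float32)
    for i, ch in enumerate(seq.upper()):
        j = _BASE_INDEX.get(ch)
        if j is not None:
            arr[j, i] = 1.0
    return arr


def predict_accessibility(seq: str, model: AccessibilityPredictor) -> AccessibilityPrediction:
    """Score one sequence; rejects inputs of the wrong length."""
    if len(seq) != model.input_length:
        raise ValueError(
            f"sequence length {len(seq)} != model input length {model.input_length}"
        )
    probs = model.predict_batch([seq])[0]
    return AccessibilityPrediction(
        {track: float(p) for track, p in zip(model.track_ids, probs)}
    )


class ConvAccessibilityModel:
    """Small convolutional accessibility classifier (numpy).

    One convolutional layer of ``n_filters`` position-weight-matrix-like
    filters, ReLU, global max pooling and a logistic output unit.  Exposes a
    single synthetic accessibility track.
    """

    track_ids: tuple[str, ...] = ("synthetic_accessibility",)

    def __init__(
        self,
        input_length: int,
        filter_width: int = 10,
        n_filters: int = 12,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.input_length = int(input_length)
        self.filter_width = int(filter_width)
        self.n_filters = int(n_filters)
        scale = 1.0 / np.sqrt(4 * filter_width)
        self.W1 = rng.normal(0.0, scale, size=(n_filters, 4, filter_width)).astype(
            np.float32
        )
        self.b1 = np.zeros(n_filters, dtype=np.float32)
        self.w2 = rng.normal(0.0, 1.0 / np.sqrt(n_filters), size=n_filters).astype(
            np.float32
        )
        self.b2 = np.float32(0.0)

    # -- forward ---------------------------------------------------------
    def _forward(self, X: np.ndarray):
        """X: (B, 4, L) -> (probabilities, cache for backprop)."""
        windows = np.lib.stride_tricks.sliding_window_view(
            X, self.filter_width, axis=2
        )  # (B, 4, P, w)
        conv = np.einsum("bcpw,kcw->bpk", windows, self.W1) + self.b1  # (B, P, K)
        relu = np.maximum(conv, 0.0)
        argmax = relu.argmax(axis=1)  # (B, K)
        b_idx = np.arange(X.shape[0])[:, None]
        pooled = relu[b_idx, argmax, np.arange(self.n_filters)]  # (B, K)
        logits = pooled @ self.w2 + self.b2
        probs = 1.0 / (1.0 + np.exp(-logits))
        cache = (windows, conv, argmax, pooled)
        return probs, cache

    def predict_batch(self, sequences: Sequence[str]) -> np.ndarray:
        out = np.empty((len(sequences), 1), dtype=np.float64)
        for lo in range(0, len(sequences), 256):
            chunk = sequences[lo : lo + 256]
            for s in chunk:
                if len(s) != self.input_length:
                    raise ValueError(
                        f"sequence length {len(s)} != model input length "
                        f"{self.input_length}"
                    )
            X = np.stack([one_hot(s) for s in chunk])
            probs, _ = self._forward(X)
            out[lo : lo + len(chunk), 0] = probs
        return out

    # -- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            W1=self.W1,
            b1=self.b1,
            w2=self.w2,
            b2=np.asarray(self.b2),
            input_length=np.asarray(self.input_length),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ConvAccessibilityModel":
        data = np.load(str(path))
        model = cls.__new__(cls)
        model.W1 = data["W1"]
        model.b1 = data["b1"]
        model.w2 = data["w2"]
        model.b2 = np.float32(data["b2"])
        model.input_length = int(data["input_length"])
        model.n_filters, _, model.filter_width = model.W1.shape
        return model


def train_reference_predictor(
    sequences: Sequence[str],
    labels: Sequence[int],
    seed: int,
    epochs: int = 25,
    batch_size: int = 128,
    learning_rate: float = 5e-3,
    filter_width: int = 10,
    n_filters: int = 12,
    holdout_frac: float = 0.2,
) -> ConvAccessibilityModel:
    """Seeded, reproducible training of the reference CNN.

    A held-out split (``holdout_frac``) is carved off before training; its
    AUROC is stored on the returned model as ``holdout_auroc``.  Rejects
    single-class datasets.
    """
    from sklearn.metrics import roc_auc_score

    y = np.asarray(labels, dtype=np.float32)
    if len(set(np.unique(y))) < 2:
        raise ValueError("training data must contain at least two classes")
    if len(sequences) != len(y):
        raise ValueError("sequences and labels must have equal length")
    L = len(sequences[0])
    for s in sequences:
        if len(s) != L:
            raise ValueError("all training sequences must share one length")

    rng = np.random.default_rng(seed)
    n = len(sequences)
    order = rng.permutation(n)
    n_hold = int(round(holdout_frac * n))
    hold_idx, train_idx = order[:n_hold], order[n_hold:]

    X = np.stack([one_hot(s) for s in sequences]).astype(np.float32)
    model = ConvAccessibilityModel(L, filter_width, n_filters, rng=rng)

    # Adam state
    params = ["W1", "b1", "w2", "b2"]
    m = {p: np.zeros_like(np.asarray(getattr(model, p), dtype=np.float32)) for p in params}
    v = {p: np.zeros_like(np.asarray(getattr(model, p), dtype=np.float32)) for p in params}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    for _epoch in range(epochs):
        perm = rng.permutation(train_idx)
        for lo in range(0, len(perm), batch_size):
            idx = perm[lo : lo + batch_size]
            Xb, yb = X[idx], y[idx]
            probs, (windows, conv, argmax, pooled) = model._forward(Xb)
            B = len(idx)

            dlogits = (probs - yb).astype(np.float32) / B  # (B,)
            grads = {
                "w2": pooled.T @ dlogits,
                "b2": np.float32(dlogits.sum()),
            }
            dpooled = np.outer(dlogits, model.w2)  # (B, K)
            b_idx = np.arange(B)[:, None]
            k_idx = np.arange(model.n_filters)
            conv_at_max = conv[b_idx, argmax, k_idx]  # (B, K)
            dpooled = dpooled * (conv_at_max > 0)  # ReLU gate
            # gather the input window behind each filter's max position
            win_bpcw = windows.transpose(0, 2, 1, 3)  # (B, P, 4, w)
            sel = np.take_along_axis(
                win_bpcw, argmax[:, :, None, None], axis=1
            )  # (B, K, 4, w)
            grads["W1"] = np.einsum("bk,bkcw->kcw", dpooled, sel).astype(np.float32)
            grads["b1"] = dpooled.sum(axis=0).astype(np.float32)

            t += 1
            for p in params:
                g = np.asarray(grads[p], dtype=np.float32)
                m[p] = beta1 * m[p] + (1 - beta1) * g
                v[p] = beta2 * v[p] + (1 - beta2) * g * g
                mhat = m[p] / (1 - beta1**t)
                vhat = v[p] / (1 - beta2**t)
                update = learning_rate * mhat / (np.sqrt(vhat) + eps)
                setattr(
                    model, p, (np.asarray(getattr(model, p), dtype=np.float32) - update)
                )
    model.b2 = np.float32(model.b2)

    if n_hold:
        hold_probs = []
        for lo in range(0, n_hold, 256):
            idx = hold_idx[lo : lo + 256]
            probs, _ = model._forward(X[idx])
            hold_probs.append(probs)
        model.holdout_auroc = float(
            roc_auc_score(y[hold_idx], np.concatenate(hold_probs))
        )
    else:
        model.holdout_auroc = None
    return model


def apply_edit(
    ref_context: str,
    spec: ProtospacerSpec,
    positions: Sequence[int],
    strand: str = "+",
) -> str:
    """Convert the named window adenines to G (protospacer strand).

    ``ref_context`` is the plus-strand reference sequence with the 20-nt
    protospacer occupying its center (offset (len-20)//2).  On a
    minus-strand site the protospacer-strand A->G edit appears on the
    reference as T->C at the mirrored coordinate.  Positions must lie in
    the editing window and carry an adenine; length is preserved.
    """
    lo, hi = spec.editing_window
    proto_start = (len(ref_context) - 20) // 2
    out = list(ref_context)
    for p in positions:
        if not (lo <= p <= hi):
            raise ValueError(f"position {p} outside editing window [{lo}, {hi}]")
        if strand == "+":
            coord = proto_start + p - 1
            if out[coord].upper() != "A":
                raise ValueError(
                    f"protospacer position {p} lacks an adenine (found {out[coord]!r})"
                )
            out[coord] = "G"
        else:
            coord = proto_start + 20 - p
            if out[coord].upper() != "T":
                raise ValueError(
                    f"protospacer position {p} lacks an adenine (reference shows "
                    f"{out[coord]!r}, expected T)"
                )
            out[coord] = "C"
    return "".join(out)


def extract_context(
    site: CandidateSite, genome: dict[str, str], input_length: int
) -> str:
    """Plus-strand reference context centered on the site's protospacer."""
    iv = site.interval
    start = iv.start - (input_length - 20) // 2
    end = start + input_length
    seq = genome[iv.contig]
    if start < 0 or end > len(seq):
        raise ValueError(
            f"site {iv.contig}:{iv.start}-{iv.end} too close to a contig edge "
            f"for a {input_length}-nt context"
        )
    return seq[start:end].upper()


def score_site(
    site: CandidateSite,
    genome: dict[str, str],
    spec: ProtospacerSpec,
    model: AccessibilityPredictor,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    damage_threshold: float = DEFAULT_DAMAGE_THRESHOLD,
    flag_absolute: bool = False,
) -> DamageResult:
    """Damage-score one candidate site.

    Evaluated edits: each single window adenine, plus the all-adenines edit
    when more than one is present.  ``max_damage`` is the signed maximum of
    (P_control - P_edited) over tracks and edits.  A site is flagged when
    any track of any edit has P_control above ``p_threshold`` and damage
    above ``damage_threshold``; with ``flag_absolute`` the magnitude of the
    damage is thresholded instead, so accessibility-gain edits also flag.
    """
    adenines = spec.window_adenines(site.matched_protospacer)
    if not adenines:
        raise ValueError("site has no adenine in the editing window")

    context = extract_context(site, genome, model.input_length)
    edit_sets: list[tuple[int, ...]] = [(p,) for p in adenines]
    if len(adenines) > 1:
        edit_sets.append(tuple(adenines))

    edited_seqs = [
        apply_edit(context, spec, positions, strand=site.interval.strand)
        for positions in edit_sets
    ]
    probs = model.predict_batch([context] + edited_seqs)
    p_control = {t: float(p) for t, p in zip(model.track_ids, probs[0])}

    edits: list[EditEvaluation] = []
    max_damage = -np.inf
    flagged = False
    for positions, row in zip(edit_sets, probs[1:]):
        p_edited = {t: float(p) for t, p in zip(model.track_ids, row)}
        damage = {t: p_control[t] - p_edited[t] for t in p_control}
        for t, d in damage.items():
            max_damage = max(max_damage, d)
            effect = abs(d) if flag_absolute else d
            if p_control[t] > p_threshold and effect > damage_threshold:
                flagged = True
        edits.append(
            EditEvaluation(
                description="+".join(f"A{p}" for p in positions),
                positions=positions,
                p_edited=p_edited,
                damage=damage,
            )
        )
    return DamageResult(
        site=site,
        p_control=p_control,
        edits=edits,
        max_damage=float(max_damage),
        flagged=flagged,
    )
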