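"""Product→reactant AE-sequence translation model.

:class:`AETranslator` is a scikit-learn-style estimator wrapping a
pre-norm transformer encoder–decoder: ``fit`` trains with teacher-forced
negative log-likelihood under Adam, selecting the best checkpoint by
validation loss; ``predict`` greedily decodes top-1 reactant AE sets,
splitting on the reactant separator token and collapsing duplicates
(the representation is a set of unique environments).  Cross-attention
weights of a teacher-forced pass are exposed for interpretability: their
column sums over target positions indicate which product environments
the model attends to most.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .chem import BOS, EOS, PAD, SEP
from .corpus import CuratedDataset, decode_target, encode_example
from .nn import autograd as ag
from .nn.layers import Ctx, Transformer

__all__ = ["AETranslator", "Prediction", "AttentionRecord", "predict_top1", "attention_maps"]

SourceTokens = list[int]
TargetBlocks = list[list[int]]


@dataclass
class Prediction:
    """Greedy top-1 decode: one or two reactant AE token sets."""

    blocks: TargetBlocks
    incomplete: bool = False  # no EOS emitted within the length cap


@dataclass
class AttentionRecord:
    """Cross-attention of one teacher-forced example.

    ``cross_attention[layer][head]`` is a (target × source) weight matrix;
    ``matrix`` is the head average of the final layer; ``column_sums`` are
    its per-source-token totals; ``alignment`` maps each target position
    to its argmax source position.
    """

    cross_attention: list[np.ndarray]
    matrix: np.ndarray
    column_sums: np.ndarray
    alignment: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "matrix": self.matrix.tolist(),
                "column_sums": self.column_sums.tolist(),
                "alignment": self.alignment,
            }
        )


def _pad_batch(seqs: list[list[int]], width: int | None = None) -> np.ndarray:
    width = width or max(len(s) for s in seqs)
    out = np.full((len(seqs), width), PAD, dtype=np.int64)
    for i, s in enumerate(seqs):
        out[i, : len(s)] = s
    return out


def _encode_target(blocks: TargetBlocks) -> list[int]:
    toks = [BOS]
    for i, block in enumerate(blocks):
        if i:
            toks.append(SEP)
        toks.extend(block)
    toks.append(EOS)
    return toks


class AETranslator(BaseEstimator):
    """Transformer translator over atom-environment token sequences.

    Parameters mirror the usual transformer knobs: ``n_layers`` encoder
    and decoder layers, ``n_heads`` attention heads, ``model_dim`` hidden
    width (divisible by ``n_heads``), ``ff_dim`` feed-forward width,
    ``dropout`` rate, sinusoidal ``positional_encoding`` on/off, ``lr``
    and ``warmup_steps`` for the Adam schedule (constant when warmup is
    0, inverse-square-root decay otherwise), ``epochs``, ``batch_size``
    and a held-out ``validation_fraction`` used only to pick the best
    checkpoint.  ``n_tokens`` is inferred from the data when left at 0.
    A single ``seed`` governs initialization, batch order and dropout.
    """

    def __init__(
        self,
        n_layers: int = 2,
        n_heads: int = 4,
        model_dim: int = 64,
        ff_dim: int = 256,
        dropout: float = 0.1,
        batch_size: int = 300,
        max_len: int = 104,
        positional_encoding: bool = True,
        tie_embedding: bool = True,
        lr: float = 1e-3,
        warmup_steps: int = 0,
        epochs: int = 30,
        validation_fraction: float = 0.1,
        n_tokens: int = 0,
        seed: int = 0,
    ):
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.model_dim = model_dim
        self.ff_dim = ff_dim
        self.dropout = dropout
        self.batch_size = batch_size
        self.max_len = max_len
        self.positional_encoding = positional_encoding
        self.tie_embedding = tie_embedding
        self.lr = lr
        self.warmup_steps = warmup_steps
        self.epochs = epochs
        self.validation_fraction = validation_fraction
        self.n_tokens = n_tokens
        self.seed = seed

    # ------------------------------------------------------------------ fit
    def fit(
        self,
        X: list[SourceTokens],
        y: list[TargetBlocks],
        X_valid: list[SourceTokens] | None = None,
        y_valid: list[TargetBlocks] | None = None,
    ) -> "AETranslator":
        """Train on (product tokens, reactant token blocks) pairs.

        A validation subset (explicit, or split off with
        ``validation_fraction``) steers best-checkpoint selection; the
        parameters of the best-validation-loss epoch are restored at the
        end of training.
        """
        if len(X) != len(y) or not X:
            raise ValueError("X and y must be equal-length and non-empty")
        targets = [_encode_target(blocks) for blocks in y]
        n_tokens = int(
            self.n_tokens
            or max(max((max(s) for s in X if s), default=0),
                   max(max(t) for t in targets)) + 1
        )
        rng = np.random.default_rng(self.seed)
        self.model_ = Transformer(
            n_tokens=n_tokens,
            n_layers=self.n_layers,
            n_heads=self.n_heads,
            model_dim=self.model_dim,
            ff_dim=self.ff_dim,
            max_len=self.max_len,
            positional_encoding=self.positional_encoding,
            tie_embedding=self.tie_embedding,
            seed=int(rng.integers(2**31)),
        )
        self.n_tokens_ = n_tokens

        if X_valid is None:
            n_valid = max(1, int(round(len(X) * self.validation_fraction))) if len(X) > 10 else 0
            order = rng.permutation(len(X))
            valid_idx, train_idx = order[:n_valid], order[n_valid:]
            X_valid = [X[i] for i in valid_idx]
            tgt_valid = [targets[i] for i in valid_idx]
            X_train = [X[i] for i in train_idx]
            tgt_train = [targets[i] for i in train_idx]
        else:
            X_train, tgt_train = list(X), targets
            tgt_valid = [_encode_target(b) for b in y_valid]

        params = self.model_.parameters()
        opt = ag.Adam(params, lr=self.lr)
        self.training_log_: list[dict] = []
        best_loss = np.inf
        best_state = None
        step = 0
        for epoch in range(1, self.epochs + 1):
            order = rng.permutation(len(X_train))
            # length-sorted buckets within a shuffled epoch keep padding low
            order = sorted(order, key=lambda i: (len(X_train[i]) // 8, rng.random()))
            losses = []
            for lo in range(0, len(order), self.batch_size):
                idx = order[lo : lo + self.batch_size]
                src = _pad_batch([X_train[i] for i in idx])
                tgt = _pad_batch([tgt_train[i] for i in idx])
                step += 1
                if self.warmup_steps:
                    opt.lr = self.lr * min(
                        step / self.warmup_steps, np.sqrt(self.warmup_steps / step)
                    )
                ctx = Ctx(train=True, dropout=self.dropout, rng=rng)
                logits = self.model_.forward(src, tgt[:, :-1], ctx)
                loss = ag.cross_entropy(logits, tgt[:, 1:], tgt[:, 1:] != PAD)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}; "
                        "last stable checkpoint retained"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            record = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if X_valid:
                v_loss, v_acc = self._eval_loss(X_valid, tgt_valid)
                record.update(valid_loss=v_loss, valid_token_acc=v_acc)
                if v_loss < best_loss:
                    best_loss = v_loss
                    best_state = copy.deepcopy(self.model_.state_arrays())
            self.training_log_.append(record)
        if best_state is not None:
            self.model_.load_state_arrays(best_state)
        return self

    def _eval_loss(self, X: list[SourceTokens], targets: list[list[int]]) -> tuple[float, float]:
        ctx = Ctx(train=False, dropout=0.0, rng=np.random.default_rng(0))
        total_loss, total_correct, total_count = 0.0, 0, 0
        for lo in range(0, len(X), self.batch_size):
            src = _pad_batch(X[lo : lo + self.batch_size])
            tgt = _pad_batch(targets[lo : lo + self.batch_size])
            logits = self.model_.forward(src, tgt[:, :-1], ctx)
            mask = tgt[:, 1:] != PAD
            loss = ag.cross_entropy(logits, tgt[:, 1:], mask)
            pred = logits.data.argmax(-1)
            total_correct += int(((pred == tgt[:, 1:]) & mask).sum())
            total_count += int(mask.sum())
            total_loss += float(loss.data) * int(mask.sum())
        return total_loss / max(total_count, 1), total_correct / max(total_count, 1)

    # -------------------------------------------------------------- predict
    def predict_detailed(self, X: list[SourceTokens]) -> list[Prediction]:
        """Greedy decode until EOS (or the length cap, flagged incomplete)."""
        self._check_fitted()
        if any(len(s) == 0 for s in X):
            raise ValueError("cannot decode an empty source sequence")
        ctx = Ctx(train=False, dropout=0.0, rng=np.random.default_rng(0))
        out: list[Prediction] = []
        for lo in range(0, len(X), self.batch_size):
            chunk = X[lo : lo + self.batch_size]
            src = _pad_batch(chunk)
            memory = self.model_.encode(src, ctx)
            batch = len(chunk)
            tgt = np.full((batch, 1), BOS, dtype=np.int64)
            finished = np.zeros(batch, dtype=bool)
            for _ in range(self.max_len - 1):
                logits = self.model_.decode(tgt, memory, src, ctx)
                nxt = logits.data[:, -1, :].argmax(-1)
                nxt[finished] = PAD
                tgt = np.concatenate([tgt, nxt[:, None]], axis=1)
                finished |= nxt == EOS
                if finished.all():
                    break
            for row, done in zip(tgt, finished):
                toks = row.tolist()
                out.append(Prediction(blocks=decode_target(toks), incomplete=not done))
        return out

    def predict(self, X: list[SourceTokens]) -> list[TargetBlocks]:
        """Top-1 predicted reactant AE token sets (one or two per product)."""
        return [p.blocks for p in self.predict_detailed(X)]

    def score(self, X: list[SourceTokens], y: list[TargetBlocks]) -> float:
        """Fraction of exact set matches (block order insensitive)."""
        preds = self.predict(X)
        hits = sum(
            _blocks_equal(p, truth) for p, truth in zip(preds, y)
        )
        return hits / len(y)

    # ------------------------------------------------------------ attention
    def attention_maps(self, source: SourceTokens, target_blocks: TargetBlocks) -> AttentionRecord:
        """Cross-attention of a teacher-forced pass over one example."""
        self._check_fitted()
        ctx = Ctx(train=False, dropout=0.0, rng=np.random.default_rng(0))
        src = _pad_batch([source])
        tgt = _pad_batch([_encode_target(target_blocks)])
        self.model_.forward(src, tgt[:, :-1], ctx, record_attention=True)
        per_layer = [w[0] for w in self.model_.cross_attention_weights()]  # H,Tq,Tk
        final = per_layer[-1].mean(axis=0)  # head average
        return AttentionRecord(
            cross_attention=per_layer,
            matrix=final,
            column_sums=final.sum(axis=0),
            alignment=final.argmax(axis=1).tolist(),
        )

    # ---------------------------------------------------------- persistence
    def save(self, path, vocab_fingerprint: str = "") -> None:
        self._check_fitted()
        path = Path(path)
        arrays = self.model_.state_arrays()
        meta = dict(
            params=self.get_params(),
            n_tokens=self.n_tokens_,
            vocab_fingerprint=vocab_fingerprint,
            training_log=getattr(self, "training_log_", []),
        )
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path, expected_vocab_fingerprint: str | None = None) -> "AETranslator":
        data = np.load(Path(path) if str(path).endswith(".npz") else str(path) + ".npz")
        meta = json.loads(bytes(data["__meta__"]).decode())
        if expected_vocab_fingerprint is not None and meta["vocab_fingerprint"] != expected_vocab_fingerprint:
            raise ValueError("checkpoint was trained with a different vocabulary")
        est = cls(**meta["params"])
        est.n_tokens_ = meta["n_tokens"]
        est.model_ = Transformer(
            n_tokens=meta["n_tokens"],
            n_layers=est.n_layers,
            n_heads=est.n_heads,
            model_dim=est.model_dim,
            ff_dim=est.ff_dim,
            max_len=est.max_len,
            positional_encoding=est.positional_encoding,
            tie_embedding=est.tie_embedding,
            seed=0,
        )
        est.model_.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
        est.training_log_ = meta["training_log"]
        est.vocab_fingerprint_ = meta["vocab_fingerprint"]
        return est

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("AETranslator is not fitted; call fit() or load()")


def _blocks_equal(pred: TargetBlocks, truth: TargetBlocks) -> bool:
    if len(pred) != len(truth):
        return False
    pred_sets = sorted(tuple(sorted(set(b))) for b in pred)
    truth_sets = sorted(tuple(sorted(set(b))) for b in truth)
    return pred_sets == truth_sets


# ---------------------------------------------------------------------------
# dataset-level conveniences

def dataset_to_xy(ds: CuratedDataset, label: str | None = None) -> tuple[list[SourceTokens], list[TargetBlocks]]:
    """Extract (source, target-blocks) pairs, optionally for one split."""
    X, y = [], []
    for ex, lab in zip(ds.examples, ds.split_labels):
        if label is not None and lab != label:
            continue
        src, _ = encode_example(ex)
        X.append(src)
        y.append([list(seq.tokens) for seq in ex.reactant_seqs])
    return X, y


def predict_top1(model: AETranslator, product_tokens: SourceTokens) -> Prediction:
    """Top-1 greedy prediction for a single product AE sequence."""
    return model.predict_detailed([product_tokens])[0]


def attention_maps(model: AETranslator, source: SourceTokens, target_blocks: TargetBlocks) -> AttentionRecord:
    return model.attention_maps(source, target_blocks)
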