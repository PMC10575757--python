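"""Per-cluster character-level LSTM generative models for CDR1-3 design.

Within one CDR3 cluster, the concatenated CDR1+CDR2+CDR3 amino-acid strings
observed after the final FACS round are treated as sentences over a
23-token vocabulary (20 residues + start/end/pad) and modeled
autoregressively by a stacked LSTM (default: two layers of 64 units, 0.2
dropout) trained with Adam on one-hot inputs.  Read redundancy is kept in
training — a sequence seen with count c contributes c (capped, rescaled)
training examples — so the model learns the FACS-selected abundance
distribution, not just the unique-sequence support.

The training epoch is selected by k-fold cross-validation over unique
sequences: the epoch with the lowest mean held-out loss wins, and the final
model is refit on all data for exactly that many epochs.

New CDR combinations are sampled autoregressively (softmax temperature,
default 1) with the total length constrained to lengths observed in
training; CDR boundaries are re-imposed from the cluster's fixed CDR1/CDR2
lengths.  Sequences (observed or sampled) are scored by their negative
log-likelihood NLL = -sum_k ln p(x_k), lower meaning more typical of the
enriched training pool.

Everything is implemented in numpy and fully deterministic under a fixed
seed.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .repertoire import AA_ALPHABET, AnnotatedVHH, SOURCE_NGS, SOURCE_SAMPLED

PAD, START, END = 0, 1, 2
TOKENS = ["<pad>", "<s>", "</s>"] + list(AA_ALPHABET)
TOKEN_INDEX = {t: i for i, t in enumerate(TOKENS)}
VOCAB_SIZE = len(TOKENS)  # 23

PROB_FLOOR = 1e-12


class GenerativeError(ValueError):
    pass


@dataclass
class GenerativeConfig:
    """Architecture and training hyperparameters.

    The defaults are the reference architecture for this workflow: a
    two-layer, 64-unit LSTM with 0.2 dropout, up to 200 epochs with 5-fold
    cross-validated epoch selection, and 10,000 samples per cluster.
    """

    num_layers: int = 2
    hidden_units: int = 64
    dropout: float = 0.2
    max_epochs: int = 200
    cv_folds: int = 5
    sample_n: int = 10000
    temperature: float = 1.0
    seed: int = 0
    count_weighting: bool = True
    learning_rate: float = 0.03
    lr_decay: bool = True  # cosine decay of the learning rate over the run
    batch_size: int = 8
    replication_cap: int = 20000

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise GenerativeError("dropout must be in [0, 1)")
        if self.temperature <= 0:
            raise GenerativeError("temperature must be positive")
        if self.cv_folds < 1:
            raise GenerativeError("cv_folds must be >= 1 (1 disables CV)")


# ---------------------------------------------------------------------------
# encoding

def encode_triplet(cdr1: str, cdr2: str, cdr3: str) -> list[int]:
    try:
        return (
            [START]
            + [TOKEN_INDEX[aa] for aa in cdr1 + cdr2 + cdr3]
            + [END]
        )
    except KeyError as exc:
        raise GenerativeError(f"unknown residue {exc.args[0]!r}") from None


def encode_sequences(
    triplets: Sequence[tuple[str, str, str]]
) -> tuple[np.ndarray, np.ndarray]:
    """Encode CDR triplets as a padded token matrix plus its one-hot tensor.

    Rows are <s> + CDR1+CDR2+CDR3 + </s>, right-padded to the batch maximum.
    Invertible on non-pad positions via :func:`decode_tokens`.
    """
    rows = [encode_triplet(*t) for t in triplets]
    width = max((len(r) for r in rows), default=2)
    tokens = np.full((len(rows), width), PAD, dtype=np.int64)
    for i, r in enumerate(rows):
        tokens[i, : len(r)] = r
    return tokens, one_hot(tokens)


def one_hot(tokens: np.ndarray) -> np.ndarray:
    out = np.zeros(tokens.shape + (VOCAB_SIZE,), dtype=np.float64)
    np.put_along_axis(out, tokens[..., None], 1.0, axis=-1)
    out[tokens == PAD] = 0.0
    return out


def decode_tokens(row: Sequence[int]) -> str:
    """Concatenated residue string for one encoded row (pads/specials dropped)."""
    return "".join(TOKENS[t] for t in row if t >= 3)


# ---------------------------------------------------------------------------
# parameters and the numerical core

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


@dataclass
class _LayerParams:
    wx: np.ndarray  # (input_dim, 4H)
    wh: np.ndarray  # (H, 4H)
    b: np.ndarray  # (4H,)


@dataclass
class _Params:
    layers: list[_LayerParams]
    wy: np.ndarray  # (H, V)
    by: np.ndarray  # (V,)

    def flat(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for lp in self.layers:
            out.extend([lp.wx, lp.wh, lp.b])
        out.extend([self.wy, self.by])
        return out


def _init_params(config: GenerativeConfig, rng: np.random.Generator) -> _Params:
    H = config.hidden_units
    layers = []
    dim = VOCAB_SIZE
    for _ in range(config.num_layers):
        scale_x = np.sqrt(6.0 / (dim + 4 * H))
        scale_h = np.sqrt(6.0 / (H + 4 * H))
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget-gate bias init
        layers.append(
            _LayerParams(
                wx=rng.uniform(-scale_x, scale_x, size=(dim, 4 * H)),
                wh=rng.uniform(-scale_h, scale_h, size=(H, 4 * H)),
                b=b,
            )
        )
        dim = H
    scale_y = np.sqrt(6.0 / (H + VOCAB_SIZE))
    return _Params(
        layers=layers,
        wy=rng.uniform(-scale_y, scale_y, size=(H, VOCAB_SIZE)),
        by=np.zeros(VOCAB_SIZE),
    )


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def _lstm_step_forward(x, h_prev, c_prev, lp: _LayerParams):
    H = lp.wh.shape[0]
    a = x @ lp.wx + h_prev @ lp.wh + lp.b
    i = _sigmoid(a[:, :H])
    f = _sigmoid(a[:, H : 2 * H])
    g = np.tanh(a[:, 2 * H : 3 * H])
    o = _sigmoid(a[:, 3 * H :])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    cache = (x, h_prev, c_prev, i, f, g, o, c)
    return h, c, cache


def _forward(
    tokens: np.ndarray,
    params: _Params,
    config: GenerativeConfig,
    train: bool = False,
    rng: np.random.Generator | None = None,
):
    """Teacher-forced forward pass.

    Inputs are tokens[:, :-1], targets tokens[:, 1:].  Returns per-step
    logits (B, T, V), the target mask, and the caches needed for backprop.
    """
    B, W = tokens.shape
    T = W - 1
    H = config.hidden_units
    x = one_hot(tokens[:, :-1])
    mask = (tokens[:, 1:] != PAD).astype(np.float64)
    h = [np.zeros((B, H)) for _ in range(config.num_layers)]
    c = [np.zeros((B, H)) for _ in range(config.num_layers)]
    caches: list[list] = [[] for _ in range(config.num_layers)]
    drop_masks: list[list] = [[] for _ in range(config.num_layers)]
    tops = np.empty((B, T, H))
    keep = 1.0 - config.dropout
    for t in range(T):
        inp = x[:, t, :]
        for l, lp in enumerate(params.layers):
            h[l], c[l], cache = _lstm_step_forward(inp, h[l], c[l], lp)
            caches[l].append(cache)
            out = h[l]
            if train and config.dropout > 0:
                dm = (rng.random(out.shape) < keep) / keep
                drop_masks[l].append(dm)
                out = out * dm
            inp = out
        tops[:, t, :] = inp
    logits = tops @ params.wy + params.by
    return logits, mask, (x, caches, drop_masks, tops)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _loss_and_dlogits(logits, targets, mask):
    probs = _softmax(logits)
    B, T, V = probs.shape
    idx = np.clip(targets, 0, V - 1)
    p_true = np.take_along_axis(probs, idx[..., None], axis=-1)[..., 0]
    n = mask.sum()
    loss = -(np.log(np.maximum(p_true, PROB_FLOOR)) * mask).sum() / n
    dlogits = probs.copy()
    np.put_along_axis(
        dlogits,
        idx[..., None],
        np.take_along_axis(dlogits, idx[..., None], axis=-1) - 1.0,
        axis=-1,
    )
    dlogits *= (mask / n)[..., None]
    return loss, dlogits


def _backward(dlogits, params: _Params, config: GenerativeConfig, fwd_cache):
    x, caches, drop_masks, tops = fwd_cache
    B, T, H = tops.shape
    L = config.num_layers
    grads = _Params(
        layers=[
            _LayerParams(
                wx=np.zeros_like(lp.wx),
                wh=np.zeros_like(lp.wh),
                b=np.zeros_like(lp.b),
            )
            for lp in params.layers
        ],
        wy=np.zeros_like(params.wy),
        by=np.zeros_like(params.by),
    )
    grads.wy = np.einsum("bth,btv->hv", tops, dlogits)
    grads.by = dlogits.sum(axis=(0, 1))
    # gradient flowing into each layer's (possibly dropped) output per step
    dtop = dlogits @ params.wy.T  # (B, T, H)
    dh_next = [np.zeros((B, H)) for _ in range(L)]
    dc_next = [np.zeros((B, H)) for _ in range(L)]
    dinp_lower = np.zeros((B, T, H))  # grad wrt layer l-1 dropped output
    for l in range(L - 1, -1, -1):
        lp = params.layers[l]
        gl = grads.layers[l]
        dh_time = np.zeros((B, H))
        dc_time = np.zeros((B, H))
        dlower = np.zeros((B, T, lp.wx.shape[0]))
        for t in range(T - 1, -1, -1):
            dout = dtop[:, t, :] if l == L - 1 else dinp_lower[:, t, :]
            if drop_masks[l]:
                dout = dout * drop_masks[l][t]
            dh = dout + dh_time
            xc, h_prev, c_prev, i, f, g, o, c = caches[l][t]
            tanh_c = np.tanh(c)
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c**2) + dc_time
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_time = dc * f
            da = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            gl.wx += xc.T @ da
            gl.wh += h_prev.T @ da
            gl.b += da.sum(axis=0)
            dh_time = da @ lp.wh.T
            dlower[:, t, :] = da @ lp.wx.T
        if l > 0:
            dinp_lower = dlower
    return grads


def _clip_grads(grads: _Params, max_norm: float = 5.0) -> None:
    flat = grads.flat()
    norm = np.sqrt(sum(float((g**2).sum()) for g in flat))
    if norm > max_norm:
        scale = max_norm / norm
        for g in flat:
            g *= scale


def _run_training(
    tokens: np.ndarray,
    params: _Params,
    config: GenerativeConfig,
    n_epochs: int,
    rng: np.random.Generator,
    val_tokens: np.ndarray | None = None,
) -> list[float]:
    """Adam training for n_epochs; returns per-epoch validation losses."""
    flat = params.flat()
    opt = _Adam(flat, config.learning_rate)
    n = tokens.shape[0]
    val_losses: list[float] = []
    for epoch in range(n_epochs):
        if config.lr_decay:
            # annealing to zero is what lets the model settle on calibrated
            # token probabilities rather than oscillating around them
            opt.lr = config.learning_rate * 0.5 * (
                1.0 + np.cos(np.pi * epoch / max(1, n_epochs))
            )
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = tokens[order[start : start + config.batch_size]]
            logits, mask, cache = _forward(
                batch, params, config, train=True, rng=rng
            )
            _, dlogits = _loss_and_dlogits(logits, batch[:, 1:], mask)
            grads = _backward(dlogits, params, config, cache)
            _clip_grads(grads)
            opt.step(flat, grads.flat())
        if val_tokens is not None:
            val_losses.append(evaluate_loss(val_tokens, params, config))
    return val_losses


def evaluate_loss(
    tokens: np.ndarray, params: _Params, config: GenerativeConfig
) -> float:
    """Mean per-token NLL (nats) without dropout."""
    total, count = 0.0, 0.0
    for start in range(0, tokens.shape[0], 256):
        batch = tokens[start : start + 256]
        logits, mask, _ = _forward(batch, params, config, train=False)
        loss, _ = _loss_and_dlogits(logits, batch[:, 1:], mask)
        total += loss * mask.sum()
        count += mask.sum()
    return total / count


# ---------------------------------------------------------------------------
# the public model bundle

@dataclass
class GenerativeModelBundle:
    config: GenerativeConfig
    selected_epoch: int
    fold_validation_losses: np.ndarray  # (folds, max_epochs)
    params: _Params
    training_length_set: set[int]
    cdr1_len: int
    cdr2_len: int
    vocabulary: tuple[str, ...] = tuple(TOKENS)

    def stepwise_probabilities(self, tokens: np.ndarray) -> np.ndarray:
        """p(next token) at every step for teacher-forced ``tokens`` (B, W)."""
        logits, _, _ = _forward(tokens, self.params, self.config, train=False)
        return _softmax(logits)


class UniformResidueModel:
    """Degenerate scorer: a fixed next-token distribution at every step.

    Useful for closed-form NLL calibration — a uniform distribution over the
    20 residues gives NLL = K ln 20 for a K-residue sequence when the end
    token is excluded from the support.
    """

    def __init__(self, probs: np.ndarray | None = None):
        if probs is None:
            probs = np.zeros(VOCAB_SIZE)
            probs[3:] = 1.0 / 20.0
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (VOCAB_SIZE,):
            raise GenerativeError("probs must have vocabulary length")
        self.probs = probs

    def stepwise_probabilities(self, tokens: np.ndarray) -> np.ndarray:
        B, W = tokens.shape
        return np.broadcast_to(self.probs, (B, W - 1, VOCAB_SIZE)).copy()


@dataclass(frozen=True)
class ScoredSequence:
    cdr1: str
    cdr2: str
    cdr3: str
    nll: float
    source: str

    @property
    def triplet(self) -> tuple[str, str, str]:
        return (self.cdr1, self.cdr2, self.cdr3)

    @property
    def concatenated(self) -> str:
        return self.cdr1 + self.cdr2 + self.cdr3


# ---------------------------------------------------------------------------
# training

def _replication_counts(weights: list[int], cap: int) -> list[int]:
    total = sum(weights)
    if total <= cap:
        return [max(1, w) for w in weights]
    return [max(1, int(w * cap / total)) for w in weights]


def _modal_len(values: Iterable[int]) -> int:
    from collections import Counter

    counts = Counter(values)
    return max(sorted(counts), key=lambda v: counts[v])


def train_generative_model(
    training: Sequence[AnnotatedVHH],
    config: GenerativeConfig | None = None,
    round_index: int = 2,
) -> GenerativeModelBundle:
    """Train a cluster model with cross-validated epoch selection.

    Training sequences are the unique CDR triplets; read redundancy in
    ``round_index`` enters through capped replication when count weighting
    is enabled.  Cross-validation folds split unique sequences (never their
    replicas), so identical sequences cannot leak across folds.
    """
    config = config or GenerativeConfig()
    unique: dict[tuple[str, str, str], int] = {}
    for s in training:
        w = s.count(round_index) if config.count_weighting else 1
        if s.triplet in unique:
            unique[s.triplet] += w
        elif w > 0 or not config.count_weighting:
            unique[s.triplet] = w
    triplets = sorted(unique)
    use_cv = config.cv_folds >= 2
    if use_cv and len(triplets) < config.cv_folds:
        raise GenerativeError(
            f"need at least cv_folds={config.cv_folds} unique sequences, "
            f"got {len(triplets)} (set cv_folds=1 to disable CV)"
        )
    weights = [unique[t] for t in triplets]
    reps = _replication_counts(weights, config.replication_cap)
    tokens, _ = encode_sequences(triplets)

    ss = np.random.SeedSequence(config.seed)
    seed_split, seed_cv, seed_final = ss.spawn(3)

    if use_cv:
        rng_split = np.random.default_rng(seed_split)
        fold_of = rng_split.permutation(len(triplets)) % config.cv_folds
        fold_losses = np.zeros((config.cv_folds, config.max_epochs))
        cv_seeds = seed_cv.spawn(config.cv_folds)
        for k in range(config.cv_folds):
            train_idx = np.flatnonzero(fold_of != k)
            val_idx = np.flatnonzero(fold_of == k)
            rep_idx = np.repeat(train_idx, [reps[i] for i in train_idx])
            rng_k = np.random.default_rng(cv_seeds[k])
            params_k = _init_params(config, rng_k)
            fold_losses[k] = _run_training(
                tokens[rep_idx],
                params_k,
                config,
                config.max_epochs,
                rng_k,
                val_tokens=tokens[val_idx],
            )
        selected_epoch = int(np.argmin(fold_losses.mean(axis=0))) + 1
    else:
        # CV disabled: no held-out record, train for the full epoch budget
        fold_losses = np.zeros((0, config.max_epochs))
        selected_epoch = config.max_epochs

    rng_f = np.random.default_rng(seed_final)
    params = _init_params(config, rng_f)
    rep_all = np.repeat(np.arange(len(triplets)), reps)
    _run_training(tokens[rep_all], params, config, selected_epoch, rng_f)

    lengths = {len(c1 + c2 + c3) for c1, c2, c3 in triplets}
    return GenerativeModelBundle(
        config=config,
        selected_epoch=selected_epoch,
        fold_validation_losses=fold_losses,
        params=params,
        training_length_set=lengths,
        cdr1_len=_modal_len(len(t[0]) for t in triplets),
        cdr2_len=_modal_len(len(t[1]) for t in triplets),
    )


# ---------------------------------------------------------------------------
# sampling and scoring

def _sample_batch(
    model: GenerativeModelBundle,
    n: int,
    temperature: float,
    rng: np.random.Generator,
    greedy: bool = False,
) -> list[str]:
    """Autoregressive batch sampling; returns concatenated residue strings."""
    config, params = model.config, model.params
    H = config.hidden_units
    max_len = max(model.training_length_set)
    h = [np.zeros((n, H)) for _ in range(config.num_layers)]
    c = [np.zeros((n, H)) for _ in range(config.num_layers)]
    current = np.full(n, START, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    outputs: list[list[int]] = [[] for _ in range(n)]
    for _ in range(max_len + 1):
        inp = one_hot(current[:, None])[:, 0, :]
        for l, lp in enumerate(params.layers):
            h[l], c[l], _ = _lstm_step_forward(inp, h[l], c[l], lp)
            inp = h[l]
        logits = inp @ params.wy + params.by
        logits[:, PAD] = -1e30
        logits[:, START] = -1e30
        if greedy:
            nxt = logits.argmax(axis=1)
        else:
            probs = _softmax(logits / temperature)
            cum = probs.cumsum(axis=1)
            cum[:, -1] = 1.0
            draws = rng.random(n)
            nxt = (draws[:, None] > cum).sum(axis=1)
        nxt = np.where(alive, nxt, PAD)
        for idx in np.flatnonzero(alive & (nxt >= 3)):
            outputs[idx].append(int(nxt[idx]))
        alive &= nxt != END
        current = np.where(alive, nxt, PAD)
        if not alive.any():
            break
    return ["".join(TOKENS[t] for t in row) for row in outputs]


def split_concatenated(
    model: GenerativeModelBundle, concatenated: str
) -> tuple[str, str, str]:
    """Re-impose CDR boundaries from the cluster's fixed CDR1/CDR2 lengths."""
    c1, c2 = model.cdr1_len, model.cdr2_len
    if len(concatenated) <= c1 + c2:
        raise GenerativeError("sampled sequence too short to split into CDRs")
    return concatenated[:c1], concatenated[c1 : c1 + c2], concatenated[c1 + c2 :]


def sample_sequences(
    model: GenerativeModelBundle,
    n: int | None = None,
    temperature: float | None = None,
    seed: int | None = None,
    max_retry_rounds: int = 10,
) -> tuple[list[tuple[str, str, str]], int]:
    """Sample n CDR triplets; returns (triplets, n_rejected_after_budget).

    Sampled concatenations whose length is not among the training lengths
    (or too short to split into CDRs) are discarded and resampled up to the
    retry budget; any shortfall is reported in the second return value.
    """
    n = model.config.sample_n if n is None else n
    temperature = model.config.temperature if temperature is None else temperature
    if n == 0:
        return [], 0
    rng = np.random.default_rng(
        np.random.SeedSequence(model.config.seed if seed is None else seed).spawn(1)[0]
    )
    accepted: list[tuple[str, str, str]] = []
    want = n
    min_len = model.cdr1_len + model.cdr2_len + 1
    for _ in range(max_retry_rounds):
        raw = _sample_batch(model, want, temperature, rng)
        for s in raw:
            if len(s) in model.training_length_set and len(s) >= min_len:
                accepted.append(split_concatenated(model, s))
        want = n - len(accepted)
        if want <= 0:
            break
    return accepted[:n], max(0, n - len(accepted))


def greedy_decode(model: GenerativeModelBundle) -> tuple[str, str, str]:
    """Argmax decoding from the start token (temperature -> 0 limit)."""
    rng = np.random.default_rng(0)
    s = _sample_batch(model, 1, 1.0, rng, greedy=True)[0]
    return split_concatenated(model, s)


def sequence_nll(model, cdr1: str, cdr2: str, cdr3: str) -> float:
    """NLL = -sum_k ln p(x_k) of one CDR triplet under the model."""
    return float(sequence_nlls(model, [(cdr1, cdr2, cdr3)])[0])


def sequence_nlls(
    model, triplets: Sequence[tuple[str, str, str]]
) -> np.ndarray:
    """Batch NLLs; the end token counts as the final step.

    ``model`` is anything exposing stepwise_probabilities(tokens), i.e. a
    trained bundle or a fixed-distribution calibration model.
    """
    if not triplets:
        return np.zeros(0)
    out = np.empty(len(triplets))
    # group by width to avoid cross-contaminating pads in batched scoring
    order = sorted(range(len(triplets)), key=lambda i: sum(map(len, triplets[i])))
    for start in range(0, len(order), 256):
        idx = order[start : start + 256]
        tokens, _ = encode_sequences([triplets[i] for i in idx])
        probs = model.stepwise_probabilities(tokens)
        targets = tokens[:, 1:]
        p_true = np.take_along_axis(
            probs, np.clip(targets, 0, VOCAB_SIZE - 1)[..., None], axis=-1
        )[..., 0]
        mask = targets != PAD
        nll = -(np.log(np.maximum(p_true, PROB_FLOOR)) * mask).sum(axis=1)
        out[idx] = nll
    return out


def rank_pool(
    training: Sequence[AnnotatedVHH],
    sampled: Sequence[tuple[str, str, str]],
    model,
) -> list[ScoredSequence]:
    """Merge observed and sampled triplets, score, and sort ascending by NLL.

    The union is deduplicated on the CDR triplet; a triplet present in both
    pools keeps source = ngs.  Ties are broken lexicographically, so the
    ranking is deterministic.
    """
    pool: dict[tuple[str, str, str], str] = {}
    for t in sampled:
        pool[tuple(t)] = SOURCE_SAMPLED
    for s in training:
        pool[s.triplet] = SOURCE_NGS
    triplets = sorted(pool)
    nlls = sequence_nlls(model, triplets)
    scored = [
        ScoredSequence(*t, nll=float(nll), source=pool[t])
        for t, nll in zip(triplets, nlls)
    ]
    scored.sort(key=lambda s: (s.nll, s.triplet))
    return scored


# ---------------------------------------------------------------------------
# persistence

def save_model(model: GenerativeModelBundle, path: str | Path) -> None:
    """Single-file archive: weights + config + CV record + vocabulary."""
    meta = {
        "config": asdict(model.config),
        "selected_epoch": model.selected_epoch,
        "training_length_set": sorted(model.training_length_set),
        "cdr1_len": model.cdr1_len,
        "cdr2_len": model.cdr2_len,
        "vocabulary": list(model.vocabulary),
    }
    arrays = {"fold_validation_losses": model.fold_validation_losses}
    for l, lp in enumerate(model.params.layers):
        arrays[f"wx{l}"] = lp.wx
        arrays[f"wh{l}"] = lp.wh
        arrays[f"b{l}"] = lp.b
    arrays["wy"] = model.params.wy
    arrays["by"] = model.params.by
    with open(path, "wb") as fh:
        np.savez(
            fh,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **arrays,
        )


def load_model(path: str | Path) -> GenerativeModelBundle:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        config = GenerativeConfig(**meta["config"])
        layers = [
            _LayerParams(
                wx=data[f"wx{l}"], wh=data[f"wh{l}"], b=data[f"b{l}"]
            )
            for l in range(config.num_layers)
        ]
        bundle = GenerativeModelBundle(
            config=config,
            selected_epoch=meta["selected_epoch"],
            fold_validation_losses=data["fold_validation_losses"],
            params=_Params(layers=layers, wy=data["wy"], by=data["by"]),
            training_length_set=set(meta["training_length_set"]),
            cdr1_len=meta["cdr1_len"],
            cdr2_len=meta["cdr2_len"],
            vocabulary=tuple(meta["vocabulary"]),
        )
    return bundle
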