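"""Multinomial-diffusion iterative refinement of peptide predictions.

A sequence of residue classes is corrupted by stochastically replacing
tokens with uniform draws (forward process); a transformer conditioned on
the encoded spectrum and the current timestep learns to predict the clean
sequence, and decoding runs the reverse chain for T = 20 steps. Decoding
draws several samples per spectrum; the sample matching the precursor mass
with the highest model log-probability is kept, falling back to the
initializing prediction when none fits.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import nn
from .chemistry import WATER, ResidueVocabulary, ppm_diff, residue_sum
from .knapsack import Prediction
from .model import EncodedSpectrum, ModelConfig, SpectrumEncoder, _concat_seq
from .ms_io import AnnotatedPSM, Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "NoiseSchedule",
    "q_sample",
    "posterior_distribution",
    "DiffusionRefiner",
    "train_refiner",
    "refine",
    "RefinementResult",
    "decode_with_selection",
]

DEFAULT_T = 20
DEFAULT_START_T = 15
DEFAULT_N_SAMPLES = 5


@dataclass(frozen=True)
class NoiseSchedule:
    """Per-step corruption probabilities of the forward process.

    ``beta[t-1]`` is the probability that step t resamples a position
    uniformly; ``alpha_bar[t]`` is the cumulative keep product with
    alpha_bar[0] = 1, strictly decreasing, and alpha_bar[T] near 0.
    """

    beta: np.ndarray  # shape (T,)
    alpha_bar: np.ndarray = field(init=False)  # shape (T+1,)

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=np.float64)
        if beta.ndim != 1 or np.any(beta <= 0) or np.any(beta >= 1):
            raise ValueError("beta must be a 1-D array with entries in (0, 1)")
        object.__setattr__(self, "beta", beta)
        ab = np.concatenate([[1.0], np.cumprod(1.0 - beta)])
        object.__setattr__(self, "alpha_bar", ab)

    @property
    def T(self) -> int:
        return int(self.beta.size)

    @classmethod
    def cosine(cls, T: int = DEFAULT_T, s: float = 0.008) -> "NoiseSchedule":
        """Cosine schedule mapped to T discrete steps."""
        t = np.arange(T + 1, dtype=np.float64)
        f = np.cos((t / T + s) / (1 + s) * np.pi / 2.0) ** 2
        ab = f / f[0]
        beta = 1.0 - ab[1:] / ab[:-1]
        return cls(beta=np.clip(beta, 1e-5, 0.999))


def q_sample(
    x0: np.ndarray,
    t: int,
    schedule: NoiseSchedule,
    K: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Closed-form forward corruption to step t.

    Each position independently keeps its class with probability
    alpha_bar_t + (1 - alpha_bar_t)/K and is otherwise uniform over the K
    classes; this marginal equals the composition of single-step
    transitions.
    """
    if not 0 <= t <= schedule.T:
        raise ValueError(f"t must be in [0, {schedule.T}], got {t}")
    x0 = np.asarray(x0, dtype=np.int64)
    ab = schedule.alpha_bar[t]
    keep = rng.random(x0.shape) < ab
    uniform = rng.integers(0, K, size=x0.shape)
    return np.where(keep, x0, uniform)


def single_step_sample(
    x: np.ndarray, beta_t: float, K: int, rng: np.random.Generator
) -> np.ndarray:
    """One forward transition: resample uniformly with probability beta_t."""
    keep = rng.random(x.shape) < (1.0 - beta_t)
    uniform = rng.integers(0, K, size=x.shape)
    return np.where(keep, x, uniform)


def posterior_distribution(
    x_t: np.ndarray,
    x0_estimate: np.ndarray,
    t: int,
    schedule: NoiseSchedule,
    K: Optional[int] = None,
) -> np.ndarray:
    """Multinomial-diffusion posterior q(x_{t-1} | x_t, x0), per position.

    ``x0_estimate`` may be hard class indices (L,) or a per-position
    categorical (L, K); rows of the result sum to 1.
    """
    if not 1 <= t <= schedule.T:
        raise ValueError(f"t must be in [1, {schedule.T}], got {t}")
    x_t = np.asarray(x_t, dtype=np.int64)
    x0_estimate = np.asarray(x0_estimate)
    if x0_estimate.ndim == 1:
        if K is None:
            raise ValueError("K required when x0_estimate is given as indices")
        x0_probs = np.zeros((x0_estimate.size, K))
        x0_probs[np.arange(x0_estimate.size), x0_estimate] = 1.0
    else:
        x0_probs = x0_estimate.astype(np.float64)
        K = x0_probs.shape[1]
    L = x_t.size
    alpha_t = 1.0 - schedule.beta[t - 1]
    ab_prev = schedule.alpha_bar[t - 1]
    xt_onehot = np.zeros((L, K))
    xt_onehot[np.arange(L), x_t] = 1.0
    theta = (alpha_t * xt_onehot + (1.0 - alpha_t) / K) * (
        ab_prev * x0_probs + (1.0 - ab_prev) / K
    )
    norm = theta.sum(axis=1, keepdims=True)
    degenerate = norm[:, 0] <= 0.0
    if np.any(degenerate):
        theta[degenerate] = xt_onehot[degenerate]
        norm = theta.sum(axis=1, keepdims=True)
    return theta / norm


# ---------------------------------------------------------------------------
# the refiner network
# ---------------------------------------------------------------------------


class DiffusionRefiner(nn.Module):
    """Spectrum-conditioned denoiser predicting x0 from (x_t, t).

    Shares the spectrum-encoder architecture with the autoregressive
    model; the decoder self-attends bidirectionally over the noised
    sequence and cross-attends to the spectrum memory extended with an
    embedding of the current timestep.
    """

    def __init__(
        self,
        config: ModelConfig,
        vocab: ResidueVocabulary,
        schedule: Optional[NoiseSchedule] = None,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.config = config
        self.vocab = vocab
        self.schedule = schedule or NoiseSchedule.cosine()
        self.K = len(vocab.tokens)
        d = config.hidden_dim
        self.encoder = SpectrumEncoder(config, rng)
        self.class_embedding = nn.Embedding(self.K + 1, d, rng)  # + padding class
        self.time_embedding = nn.Embedding(self.schedule.T + 1, d, rng)
        self.decoder_layers = [
            nn.TransformerLayer(d, config.heads, config.ff_dim, rng, cross=True)
            for _ in range(config.decoder_layers)
        ]
        self.decoder_norm = nn.LayerNorm(d)
        self.out_proj = nn.Linear(d, self.K, rng)
        self._pos = nn.positional_encoding(config.max_peptide_len + 2, d)
        # empirical peptide-length distribution, filled in by training;
        # used to draw a length when refining from pure noise
        self.length_counts: Counter = Counter()

    def class_of(self, tokens: Sequence[str]) -> np.ndarray:
        lookup = {t: i for i, t in enumerate(self.vocab.tokens)}
        return np.array([lookup[t] for t in tokens], dtype=np.int64)

    def tokens_of(self, classes: np.ndarray) -> Tuple[str, ...]:
        return tuple(self.vocab.tokens[int(c)] for c in classes)

    def denoise_logits(
        self,
        x_t: np.ndarray,
        t: np.ndarray,
        encoded: EncodedSpectrum,
        pad_mask: Optional[np.ndarray] = None,
    ) -> nn.Tensor:
        """Predict x0 logits (B, L, K) from noised classes x_t at steps t."""
        x_t = np.atleast_2d(np.asarray(x_t, dtype=np.int64))
        t = np.asarray(t, dtype=np.int64).reshape(-1)
        B, L = x_t.shape
        x = self.class_embedding(x_t) + nn.Tensor(self._pos[:L])
        t_tok = self.time_embedding(t).reshape(B, 1, self.config.hidden_dim)
        context = _concat_seq([encoded.memory, t_tok])
        cross_pad = np.concatenate(
            [encoded.pad_mask, np.zeros((B, 1), dtype=bool)], axis=1
        )
        cross_mask = cross_pad[:, None, None, :]
        self_mask = None
        if pad_mask is not None:
            self_mask = pad_mask[:, None, None, :]
        for layer in self.decoder_layers:
            x = layer(x, self_mask=self_mask, context=context, cross_mask=cross_mask)
        x = self.decoder_norm(x)
        return self.out_proj(x)

    def sequence_log_prob(
        self, classes: np.ndarray, encoded: EncodedSpectrum
    ) -> Tuple[float, np.ndarray]:
        """Model log-probability of a clean sequence (evaluated at t = 1).

        This is the surrogate confidence of a refined prediction; it is a
        lower-bound-style score, not calibrated against autoregressive
        confidences.
        """
        logits = self.denoise_logits(classes[None, :], np.array([1]), encoded)
        logp = nn.log_softmax_np(logits.data[0].astype(np.float64), axis=-1)
        per_pos = logp[np.arange(classes.size), classes]
        return float(per_pos.sum()), per_pos

    def save(self, path: str | Path) -> None:
        lengths = sorted(self.length_counts.items())
        np.savez_compressed(
            path,
            __config__=np.frombuffer(self.config.to_yaml().encode(), dtype=np.uint8),
            __beta__=self.schedule.beta,
            __lengths__=np.array(lengths, dtype=np.int64).reshape(-1, 2),
            **self.state_dict(),
        )

    @classmethod
    def load(cls, path: str | Path) -> "DiffusionRefiner":
        with np.load(path) as data:
            cfg = ModelConfig.from_yaml(bytes(data["__config__"]).decode())
            vocab = ResidueVocabulary.default(cfg.fixed_carbamidomethyl)
            schedule = NoiseSchedule(beta=data["__beta__"])
            model = cls(cfg, vocab, schedule, seed=0)
            model.length_counts = Counter(
                {int(l): int(c) for l, c in data["__lengths__"]}
            )
            reserved = {"__config__", "__beta__", "__lengths__"}
            model.load_state_dict(
                {k: v for k, v in data.items() if k not in reserved}
            )
        return model


def train_refiner(
    dataset: Sequence[AnnotatedPSM],
    config: ModelConfig,
    schedule: Optional[NoiseSchedule] = None,
    epochs: int = 10,
    seed: int = 0,
    lr: float = 1e-3,
    batch_size: int = 64,
    vocab: Optional[ResidueVocabulary] = None,
    refiner: Optional[DiffusionRefiner] = None,
) -> Tuple[DiffusionRefiner, List[float]]:
    """Train the denoiser: x0-prediction cross-entropy at random steps.

    For each batch a timestep t ~ U{1..T} is drawn per sequence, the clean
    peptide is corrupted with the closed-form forward marginal, and the
    model is trained to recover the clean residues (the simple surrogate
    for the variational bound). Fully seeded.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("training dataset is empty")
    vocab = vocab or ResidueVocabulary.default(config.fixed_carbamidomethyl)
    schedule = schedule or NoiseSchedule.cosine()
    if refiner is None:
        refiner = DiffusionRefiner(config, vocab, schedule, seed=seed)
    refiner.length_counts.update(len(p.peptide) for p in dataset)
    rng = np.random.default_rng(seed + 17)
    opt = nn.Adam(refiner.parameters(), lr=lr)
    K = refiner.K
    pad_class = K  # embedding row reserved for padding positions
    trace: List[float] = []
    n = len(dataset)
    for epoch in range(epochs):
        order = rng.permutation(n)
        total, count = 0.0, 0
        for start in range(0, n, batch_size):
            batch = [dataset[i] for i in order[start : start + batch_size]]
            B = len(batch)
            L = max(len(p.peptide) for p in batch)
            x0 = np.full((B, L), pad_class, dtype=np.int64)
            mask = np.zeros((B, L), dtype=bool)
            for i, psm in enumerate(batch):
                cls = refiner.class_of(psm.peptide)
                x0[i, : cls.size] = cls
                mask[i, : cls.size] = True
            t = rng.integers(1, schedule.T + 1, size=B)
            x_t = x0.copy()
            for i in range(B):
                real = mask[i]
                x_t[i, real] = q_sample(x0[i, real], int(t[i]), schedule, K, rng)
            encoded = refiner.encoder.encode_spectrum([p.spectrum for p in batch])
            logits = refiner.denoise_logits(x_t, t, encoded, pad_mask=~mask)
            tgt = np.where(mask, x0, 0)
            loss = nn.cross_entropy_logits(logits, tgt, mask)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * B
            count += B
        trace.append(total / count)
        logger.info("refiner epoch %d mean loss %.4f", epoch, trace[-1])
    return refiner, trace


# ---------------------------------------------------------------------------
# reverse-chain decoding
# ---------------------------------------------------------------------------


def refine(
    spectrum: Spectrum,
    init: Optional[Sequence[str]],
    start_t: int,
    schedule: NoiseSchedule,
    refiner: DiffusionRefiner,
    rng: np.random.Generator,
    encoded: Optional[EncodedSpectrum] = None,
    noise_init: bool = False,
) -> Tuple[Tuple[str, ...], float, int]:
    """Run the reverse chain from start_t down to 0.

    With no ``init`` the chain starts from uniform noise at t = T at a
    length drawn from the training length distribution. With an ``init``
    the (by default uncorrupted) sequence is injected at ``start_t``; set
    ``noise_init`` to corrupt it to q(x_{start_t} | x_0) first. Returns
    (residue tokens, model log-probability, steps run).
    """
    T = schedule.T
    if init is None:
        if start_t != T:
            raise ValueError("refinement from noise must start at t = T")
        if not refiner.length_counts:
            raise ValueError("refiner has no length distribution; train it first")
        lengths, counts = zip(*sorted(refiner.length_counts.items()))
        p = np.array(counts, dtype=np.float64)
        L = int(rng.choice(lengths, p=p / p.sum()))
        x = rng.integers(0, refiner.K, size=L)
    else:
        if start_t > T:
            raise ValueError(f"start_t {start_t} exceeds T = {T}")
        x = refiner.class_of(list(init))
        if noise_init and start_t > 0:
            x = q_sample(x, start_t, schedule, refiner.K, rng)
    if encoded is None:
        encoded = refiner.encoder.encode_spectrum([spectrum])
    steps = 0
    for t in range(start_t, 0, -1):
        logits = refiner.denoise_logits(x[None, :], np.array([t]), encoded)
        x0_probs = np.exp(nn.log_softmax_np(logits.data[0].astype(np.float64), axis=-1))
        post = posterior_distribution(x, x0_probs, t, schedule)
        cum = post.cumsum(axis=1)
        u = rng.random((x.size, 1))
        x = (u < cum).argmax(axis=1)
        steps += 1
    log_prob, _ = refiner.sequence_log_prob(x, encoded)
    return refiner.tokens_of(x), log_prob, steps


@dataclass
class RefinementResult:
    """Outcome of sample-and-select decoding for one spectrum."""

    peptide: Tuple[str, ...]
    log_prob: float
    n_steps_run: int
    source: str  # "refined" | "fallback"
    mass_valid: bool = True

    def __post_init__(self) -> None:
        self.peptide = tuple(self.peptide)
        if self.source not in ("refined", "fallback"):
            raise ValueError(f"unknown source {self.source!r}")


def decode_with_selection(
    spectrum: Spectrum,
    in_prediction: Optional[Prediction],
    refiner: DiffusionRefiner,
    schedule: Optional[NoiseSchedule] = None,
    n_samples: int = DEFAULT_N_SAMPLES,
    tol_ppm: float = 50.0,
    seed: int = 0,
    start_t: int = DEFAULT_START_T,
    rng: Optional[np.random.Generator] = None,
    noise_init: bool = False,
) -> RefinementResult:
    """Draw refined samples and select by precursor mass + log-probability.

    Samples start from the initializing prediction at t = start_t (default
    15) when given, else from uniform noise at t = T. Among samples whose
    residue mass lies within ``tol_ppm`` of the precursor residue mass the
    highest-log-probability one is returned; with no mass-valid sample the
    initializing prediction is the fallback (or, with no initialization,
    the best sample flagged as mass-violating).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    schedule = schedule or refiner.schedule
    rng = rng if rng is not None else np.random.default_rng(seed)
    vocab = refiner.vocab
    target = spectrum.precursor_mass - WATER
    window = tol_ppm * 1e-6 * target
    init = in_prediction.peptide if in_prediction is not None else None
    t0 = start_t if in_prediction is not None else schedule.T
    encoded = refiner.encoder.encode_spectrum([spectrum])

    samples: List[Tuple[Tuple[str, ...], float, int]] = []
    for _ in range(n_samples):
        samples.append(
            refine(
                spectrum, init, t0, schedule, refiner, rng,
                encoded=encoded, noise_init=noise_init,
            )
        )
    valid = [
        s for s in samples if abs(residue_sum(s[0], vocab) - target) <= window
    ]
    if valid:
        pep, lp, steps = max(valid, key=lambda s: (s[1], s[0]))
        return RefinementResult(
            peptide=pep, log_prob=lp, n_steps_run=steps, source="refined"
        )
    if in_prediction is not None:
        lp, _ = refiner.sequence_log_prob(
            refiner.class_of(list(in_prediction.peptide)), encoded
        )
        return RefinementResult(
            peptide=tuple(in_prediction.peptide),
            log_prob=lp,
            n_steps_run=samples[0][2] if samples else 0,
            source="fallback",
            mass_valid=abs(residue_sum(in_prediction.peptide, vocab) - target) <= window,
        )
    pep, lp, steps = max(samples, key=lambda s: (s[1], s[0]))
    return RefinementResult(
        peptide=pep, log_prob=lp, n_steps_run=steps, source="refined", mass_valid=False
    )


def refinement_to_prediction(
    spectrum: Spectrum, result: RefinementResult, vocab: ResidueVocabulary
) -> Prediction:
    """Package a refinement result as a standard prediction row."""
    target = spectrum.precursor_mass - WATER
    mass = residue_sum(result.peptide, vocab)
    n = max(len(result.peptide), 1)
    return Prediction(
        spectrum_id=spectrum.id,
        peptide=result.peptide,
        per_residue_log_probs=tuple([result.log_prob / n] * len(result.peptide)),
        log_prob=result.log_prob,
        model_tag="diff",
        precursor_ppm_error=ppm_diff(mass, target) if target > 0 else float("nan"),
    )
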