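"""The autoregressive spectrum-to-peptide transformer.

Peaks are encoded with multi-scale sinusoidal embeddings of m/z (plus a
learned lift of intensity), self-attend through a transformer encoder, and
are concatenated with a learnt latent-spectrum token and a precursor token
(sinusoidal mass encoding + learned charge embedding). A causal
transformer decoder cross-attends to this memory and predicts the peptide
one residue at a time. Decoding runs C-terminal-first (right to left) by
default, since tryptic y-ions dominate HCD spectra; predictions are
reversed back to N->C order on output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import nn
from .chemistry import ResidueVocabulary
from .ms_io import AnnotatedPSM, Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "EncodedSpectrum",
    "SpectrumEncoder",
    "AutoregressiveSequencer",
    "train_model",
]


@dataclass
class ModelConfig:
    """Geometry and encoding choices of the sequencing transformer.

    The full-scale geometry (9+9 layers, 16 heads, hidden 768, FF 1024)
    must be constructible; ``ModelConfig.toy()`` is the desk-scale preset
    actually trained in the test suite.
    """

    encoder_layers: int = 9
    decoder_layers: int = 9
    heads: int = 16
    hidden_dim: int = 768
    ff_dim: int = 1024
    max_peptide_len: int = 30
    wavelength_min: float = 0.001
    wavelength_max: float = 10000.0
    max_charge: int = 6
    precursor_mode: str = "token"  # "token": extra memory position; "sos": start token
    decode_direction: str = "rtl"  # "rtl" (C-terminal first) or "ltr"
    decoder_pos: str = "mass"  # "mass": cumulative-residue-mass encoding; "index"
    cross_attn_init: str = "uniform"  # or "identity" (matched-filter q/k start)
    fixed_carbamidomethyl: bool = True

    def __post_init__(self) -> None:
        if self.hidden_dim % self.heads:
            raise ValueError("hidden_dim must be divisible by heads")
        if self.precursor_mode not in ("token", "sos"):
            raise ValueError(f"unknown precursor_mode {self.precursor_mode!r}")
        if self.decode_direction not in ("rtl", "ltr"):
            raise ValueError(f"unknown decode_direction {self.decode_direction!r}")
        if self.decoder_pos not in ("mass", "mass2", "index"):
            raise ValueError(f"unknown decoder_pos {self.decoder_pos!r}")

    @classmethod
    def toy(cls, **overrides) -> "ModelConfig":
        """Small geometry that trains in minutes on one CPU."""
        kw = dict(encoder_layers=2, decoder_layers=2, heads=4, hidden_dim=64, ff_dim=128)
        kw.update(overrides)
        return cls(**kw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        return cls(**yaml.safe_load(text))


@dataclass
class EncodedSpectrum:
    """Encoder output: memory of length N_peaks + 2 (peaks ++ latent ++
    precursor) with a validity mask (True = padding)."""

    memory: "nn.Tensor"
    pad_mask: np.ndarray  # (B, S) True where padding
    precursor: Optional["nn.Tensor"] = None  # (B, 1, d), for "sos" conditioning
    precursor_masses: Optional[np.ndarray] = None  # (B,) neutral Da

    @property
    def length(self) -> int:
        return self.memory.shape[1]


class SpectrumEncoder(nn.Module):
    """Peak encoder shared by the autoregressive and diffusion models."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        d = config.hidden_dim
        self.intensity_lift = nn.Linear(1, d, rng)
        self.encoder_layers = [
            nn.TransformerLayer(d, config.heads, config.ff_dim, rng)
            for _ in range(config.encoder_layers)
        ]
        self.encoder_norm = nn.LayerNorm(d)
        self.latent_token = nn.Parameter(rng.normal(0.0, 0.02, size=(d,)))
        # row 0 is the unknown-charge embedding
        self.charge_embedding = nn.Embedding(config.max_charge + 1, d, rng)

    def embed_peaks(self, spectrum: Spectrum) -> np.ndarray:
        """Per-peak input vectors: sinusoidal m/z encoding + intensity lift.

        The sinusoidal part spans geometrically spaced wavelengths in
        [wavelength_min, wavelength_max] and is bounded in [-1, 1]; the
        (base-peak-normalized) intensity enters through a learned linear
        lift of log1p(intensity), keeping the representation monotone in
        intensity.
        """
        cfg = self.config
        sin = nn.sinusoidal_embedding(
            spectrum.mz, cfg.hidden_dim, cfg.wavelength_min, cfg.wavelength_max
        )
        inten = np.log1p(spectrum.intensity.astype(np.float32))[:, None]
        lift = inten @ self.intensity_lift.w.data + self.intensity_lift.b.data
        return sin + lift

    def mz_encoding(self, mz: np.ndarray) -> np.ndarray:
        """Sinusoidal-only component of the peak embedding (no intensity)."""
        cfg = self.config
        return nn.sinusoidal_embedding(
            mz, cfg.hidden_dim, cfg.wavelength_min, cfg.wavelength_max
        )

    def encode_precursor(self, mass: float, charge: int) -> np.ndarray:
        """Precursor token: sinusoidal mass encoding + learned charge row."""
        vec = self._precursor_tensor(np.array([mass]), np.array([charge]))
        return vec.data[0]

    def _charge_rows(self, charges: np.ndarray) -> np.ndarray:
        rows = charges.copy()
        bad = (rows < 1) | (rows > self.config.max_charge)
        if np.any(bad):
            warnings.warn(
                f"precursor charge outside 1..{self.config.max_charge}; "
                "using the unknown-charge embedding",
                stacklevel=3,
            )
        rows[bad] = 0
        return rows

    def _precursor_tensor(self, masses: np.ndarray, charges: np.ndarray) -> nn.Tensor:
        cfg = self.config
        sin = nn.sinusoidal_embedding(
            masses, cfg.hidden_dim, cfg.wavelength_min, cfg.wavelength_max
        )
        return self.charge_embedding(self._charge_rows(charges)) + nn.Tensor(sin)

    def encode_spectrum(self, spectra: Sequence[Spectrum]) -> EncodedSpectrum:
        """Run the encoder over a batch; memory length = max N_peaks + 2."""
        B = len(spectra)
        d = self.config.hidden_dim
        cfg = self.config
        N = max(s.n_peaks for s in spectra)
        sin = np.zeros((B, N, d), dtype=np.float32)
        inten = np.zeros((B, N, 1), dtype=np.float32)
        pad = np.ones((B, N), dtype=bool)
        for i, s in enumerate(spectra):
            sin[i, : s.n_peaks] = nn.sinusoidal_embedding(
                s.mz, d, cfg.wavelength_min, cfg.wavelength_max
            )
            inten[i, : s.n_peaks, 0] = np.log1p(s.intensity)
            pad[i, : s.n_peaks] = False
        x = nn.Tensor(sin) + self.intensity_lift(nn.Tensor(inten))
        attn_mask = pad[:, None, None, :]  # (B,1,1,N): keys at padding masked
        for layer in self.encoder_layers:
            x = layer(x, self_mask=attn_mask)
        x = self.encoder_norm(x)

        masses = np.array([s.precursor_mass for s in spectra])
        charges = np.array([s.precursor_charge for s in spectra])
        prec = self._precursor_tensor(masses, charges).reshape(B, 1, d)
        latent = self.latent_token.reshape(1, 1, d) + nn.Tensor(np.zeros((B, 1, d), np.float32))
        # zero out padded peak positions so they carry no signal downstream
        x = x * nn.Tensor((~pad[:, :, None]).astype(np.float32))
        mem_parts = [x, latent, prec]
        memory = _concat_seq(mem_parts)
        mem_pad = np.concatenate([pad, np.zeros((B, 2), dtype=bool)], axis=1)
        return EncodedSpectrum(
            memory=memory, pad_mask=mem_pad, precursor=prec, precursor_masses=masses
        )


class AutoregressiveSequencer(nn.Module):
    """Transformer encoder-decoder producing next-residue distributions."""

    def __init__(self, config: ModelConfig, vocab: ResidueVocabulary, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.vocab = vocab
        self.token_index = vocab.index()
        d = config.hidden_dim
        self.encoder = SpectrumEncoder(config, rng)
        self.token_embedding = nn.Embedding(len(vocab), d, rng)
        self.decoder_layers = [
            nn.TransformerLayer(
                d, config.heads, config.ff_dim, rng, cross=True,
                cross_qk_init=config.cross_attn_init,
            )
            for _ in range(config.decoder_layers)
        ]
        self.decoder_norm = nn.LayerNorm(d)
        self.out_proj = nn.Linear(d, len(vocab), rng)
        self._pos = nn.positional_encoding(config.max_peptide_len + 2, d)
        # token id -> residue mass (0 for specials), for mass positions
        self._token_mass = np.zeros(len(vocab), dtype=np.float64)
        for tok, i in self.token_index.items():
            self._token_mass[i] = vocab.masses.get(tok, 0.0)

    def _decoder_positions(
        self, tokens: np.ndarray, encoded: Optional[EncodedSpectrum] = None
    ) -> np.ndarray:
        """Positional input for the decoder.

        "mass" encodes the cumulative residue mass of the decoded prefix
        with the same multi-scale sinusoidal family as the peaks, so
        queries live in the same phase space as y-ion keys; "mass2"
        splits the channels between the cumulative mass and the REMAINING
        residue mass (precursor minus prefix), which additionally makes
        b-ion matching and the stop decision linear; "index" is the
        standard transformer positional encoding.
        """
        B, T = tokens.shape
        cfg = self.config
        if cfg.decoder_pos == "index":
            return np.broadcast_to(self._pos[:T], (B, T, cfg.hidden_dim))
        cum = np.cumsum(self._token_mass[tokens], axis=1)  # includes current token
        if cfg.decoder_pos == "mass":
            return nn.sinusoidal_embedding(
                cum, cfg.hidden_dim, cfg.wavelength_min, cfg.wavelength_max
            )
        half = cfg.hidden_dim // 2
        out = np.empty((B, T, cfg.hidden_dim), dtype=np.float32)
        out[..., :half] = nn.sinusoidal_embedding(
            cum, half, cfg.wavelength_min, cfg.wavelength_max
        )
        if encoded is not None and encoded.precursor_masses is not None:
            from .chemistry import WATER

            remaining = (encoded.precursor_masses - WATER)[:, None] - cum
        else:
            remaining = -cum
        out[..., half:] = nn.sinusoidal_embedding(
            remaining, half, cfg.wavelength_min, cfg.wavelength_max
        )
        return out

    # encoder surface (delegated)
    def embed_peaks(self, spectrum: Spectrum) -> np.ndarray:
        return self.encoder.embed_peaks(spectrum)

    def mz_encoding(self, mz: np.ndarray) -> np.ndarray:
        return self.encoder.mz_encoding(mz)

    def encode_precursor(self, mass: float, charge: int) -> np.ndarray:
        return self.encoder.encode_precursor(mass, charge)

    def encode_spectrum(self, spectra: Sequence[Spectrum]) -> EncodedSpectrum:
        return self.encoder.encode_spectrum(spectra)

    # ------------------------------------------------------------------ #
    # decoding
    # ------------------------------------------------------------------ #

    def decoder_logits(self, tokens: np.ndarray, encoded: EncodedSpectrum) -> nn.Tensor:
        """Teacher-forced decoder pass.

        tokens: (B, T) integer ids beginning with the start token.
        Returns logits (B, T, V); row t is the distribution for the token
        following position t (causal masking).
        """
        B, T = tokens.shape
        x = self.token_embedding(tokens) + nn.Tensor(
            self._decoder_positions(tokens, encoded)
        )
        if self.config.precursor_mode == "sos" and encoded.precursor is not None:
            # precursor conditioning injected through the start token
            pad_tail = nn.Tensor(np.zeros((B, T - 1, x.shape[-1]), np.float32))
            x = x + _concat_seq([encoded.precursor, pad_tail])
        causal = np.triu(np.ones((T, T), dtype=bool), k=1)[None, None]
        cross_mask = encoded.pad_mask[:, None, None, :]
        for layer in self.decoder_layers:
            x = layer(x, self_mask=causal, context=encoded.memory, cross_mask=cross_mask)
        x = self.decoder_norm(x)
        return self.out_proj(x)

    def next_token_logits(
        self, encoded: EncodedSpectrum, prefixes: np.ndarray
    ) -> np.ndarray:
        """Scores over the vocabulary for the next token after each prefix.

        prefixes: (B, L) residue ids (decoding order), NOT including the
        start token; L may be 0. Returns raw logits (B, V).
        """
        B = prefixes.shape[0]
        if prefixes.shape[1] >= self.config.max_peptide_len + 1:
            raise ValueError("prefix exceeds the maximum peptide length")
        sos = np.full((B, 1), self.token_index[self.vocab.sos], dtype=np.int64)
        tokens = np.concatenate([sos, prefixes.astype(np.int64)], axis=1)
        logits = self.decoder_logits(tokens, encoded)
        return logits.data[:, -1, :].astype(np.float64)

    def greedy_rollout(self, spectrum: Spectrum, max_len: Optional[int] = None) -> List[str]:
        """Unconstrained argmax decoding; returns residue tokens N->C."""
        max_len = max_len or self.config.max_peptide_len
        encoded = self.encode_spectrum([spectrum])
        eos = self.token_index[self.vocab.eos]
        prefix = np.zeros((1, 0), dtype=np.int64)
        out: List[int] = []
        for _ in range(max_len):
            logits = self.next_token_logits(encoded, prefix)[0]
            logits[self.token_index[self.vocab.pad]] = -np.inf
            logits[self.token_index[self.vocab.sos]] = -np.inf
            nxt = int(np.argmax(logits))
            if nxt == eos:
                break
            out.append(nxt)
            prefix = np.array([out], dtype=np.int64)
        id2tok = {i: t for t, i in self.token_index.items()}
        toks = [id2tok[i] for i in out]
        return toks[::-1] if self.config.decode_direction == "rtl" else toks

    # ------------------------------------------------------------------ #
    # persistence
    # ------------------------------------------------------------------ #

    def save(self, path: str | Path) -> None:
        state = self.state_dict()
        np.savez_compressed(
            path,
            __config__=np.frombuffer(self.config.to_yaml().encode(), dtype=np.uint8),
            **state,
        )

    @classmethod
    def load(cls, path: str | Path) -> "AutoregressiveSequencer":
        with np.load(path) as data:
            cfg = ModelConfig.from_yaml(bytes(data["__config__"]).decode())
            vocab = ResidueVocabulary.default(cfg.fixed_carbamidomethyl)
            model = cls(cfg, vocab, seed=0)
            model.load_state_dict({k: v for k, v in data.items() if k != "__config__"})
        return model


def _concat_seq(parts: List["nn.Tensor"]) -> "nn.Tensor":
    """Concatenate tensors along axis 1 with gradient routing."""
    data = np.concatenate([p.data for p in parts], axis=1)
    out = nn.Tensor(data)
    out._parents = tuple(parts)
    sizes = [p.data.shape[1] for p in parts]

    def bwd(g):
        start = 0
        for p, size in zip(parts, sizes):
            p._accumulate(g[:, start : start + size])
            start += size

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def encode_targets(
    model: AutoregressiveSequencer, peptides: Sequence[Sequence[str]]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build (decoder input, target, mask) id arrays for teacher forcing."""
    idx = model.token_index
    vocab = model.vocab
    rtl = model.config.decode_direction == "rtl"
    T = max(len(p) for p in peptides) + 1  # + end-of-sequence
    B = len(peptides)
    inp = np.full((B, T), idx[vocab.pad], dtype=np.int64)
    tgt = np.full((B, T), idx[vocab.pad], dtype=np.int64)
    mask = np.zeros((B, T), dtype=bool)
    inp[:, 0] = idx[vocab.sos]
    for i, pep in enumerate(peptides):
        toks = list(pep)[::-1] if rtl else list(pep)
        ids = [idx[t] for t in toks]
        inp[i, 1 : 1 + len(ids)] = ids
        tgt[i, : len(ids)] = ids
        tgt[i, len(ids)] = idx[vocab.eos]
        mask[i, : len(ids) + 1] = True
    return inp, tgt, mask


def train_model(
    dataset: Sequence[AnnotatedPSM],
    config: ModelConfig,
    epochs: int = 10,
    seed: int = 0,
    lr: float = 1e-3,
    batch_size: int = 64,
    vocab: Optional[ResidueVocabulary] = None,
    model: Optional[AutoregressiveSequencer] = None,
    weight_decay: float = 0.0,
    label_smoothing: float = 0.0,
    lr_schedule: str = "constant",  # or "cosine" (5% linear warmup)
    log_every: int = 0,
) -> Tuple[AutoregressiveSequencer, List[float]]:
    """Train by token-level cross-entropy against the ground-truth peptide.

    Returns the trained model and the per-epoch mean loss trace. Fully
    seeded: a fixed seed gives a bit-identical trace on one machine.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("training dataset is empty")
    for psm in dataset:
        if len(psm.peptide) > config.max_peptide_len:
            raise ValueError(
                f"peptide of length {len(psm.peptide)} exceeds max_peptide_len"
            )
    vocab = vocab or ResidueVocabulary.default(config.fixed_carbamidomethyl)
    if model is None:
        model = AutoregressiveSequencer(config, vocab, seed=seed)
    rng = np.random.default_rng(seed + 1)
    opt = nn.Adam(model.parameters(), lr=lr, weight_decay=weight_decay)
    trace: List[float] = []
    n = len(dataset)
    steps_per_epoch = (n + batch_size - 1) // batch_size
    total_steps = max(epochs * steps_per_epoch, 1)
    warmup = max(int(0.05 * total_steps), 1)
    step_idx = 0
    for epoch in range(epochs):
        order = rng.permutation(n)
        total, count = 0.0, 0
        for start in range(0, n, batch_size):
            if lr_schedule == "cosine":
                if step_idx < warmup:
                    opt.lr = lr * (step_idx + 1) / warmup
                else:
                    frac = (step_idx - warmup) / max(total_steps - warmup, 1)
                    opt.lr = lr * (0.1 + 0.9 * 0.5 * (1 + np.cos(np.pi * frac)))
            step_idx += 1
            batch = [dataset[i] for i in order[start : start + batch_size]]
            spectra = [p.spectrum for p in batch]
            encoded = model.encode_spectrum(spectra)
            inp, tgt, mask = encode_targets(model, [p.peptide for p in batch])
            logits = model.decoder_logits(inp, encoded)
            loss = nn.cross_entropy_logits(logits, tgt, mask, label_smoothing)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(batch)
            count += len(batch)
            if log_every and (start // batch_size) % log_every == 0:
                logger.info("epoch %d step %d loss %.4f", epoch, start // batch_size, loss.data)
        trace.append(total / count)
        logger.info("epoch %d mean loss %.4f", epoch, trace[-1])
    return model, trace
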