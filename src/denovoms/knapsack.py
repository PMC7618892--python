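"""Mass-constrained decoding: residue-mass reachability + beam search.

The knapsack table answers "can some residue multiset sum to this mass?"
on a discretized grid. During beam search every expansion whose remaining
mass budget cannot be completed by any residue multiset is pruned, and the
end-of-sequence token is only admissible when the remaining budget is
within the ppm window of zero. All masses in this module are RESIDUE-SUM
masses: the precursor's neutral mass minus water. This avoids the classic
water/proton off-by-one.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import nn
from .chemistry import WATER, ResidueVocabulary, ppm_diff
from .ms_io import Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "KnapsackTable",
    "build_table",
    "is_continuable",
    "Prediction",
    "knapsack_beam_search",
]

DEFAULT_RESOLUTION = 0.0005  # Da per bin
DEFAULT_PPM_TOL = 50.0
_EDGE_BINS = 8  # feasibility-window inset, in bins (see is_continuable)


UNREACHABLE = 255  # sentinel in the min-residue-count array


@dataclass
class KnapsackTable:
    """Reachability over discretized residue-sum masses.

    ``min_count[b]`` is the minimum number of residues in any multiset
    whose total mass falls in bin ``b`` (255 = unreachable);
    ``reachable[b]`` is its boolean shadow. Bin 0 (the empty multiset) is
    always reachable, and the reachable set is closed under adding any
    residue mass up to ``max_mass``. Knowing the minimal count lets beam
    search prune paths that could only finish by exceeding the remaining
    length budget.
    """

    resolution: float
    max_mass: float
    min_count: np.ndarray  # uint8, len n_bins
    residue_bins: Dict[str, int] = field(default_factory=dict)

    @property
    def reachable(self) -> np.ndarray:
        return self.min_count < UNREACHABLE

    @property
    def n_bins(self) -> int:
        return int(self.min_count.size)

    def bin_of(self, mass: float) -> int:
        return int(round(mass / self.resolution))

    # -- disk cache --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            min_count=self.min_count,
            resolution=self.resolution,
            max_mass=self.max_mass,
        )

    @classmethod
    def load(cls, path: str | Path, vocab: ResidueVocabulary) -> "KnapsackTable":
        with np.load(path) as data:
            table = cls(
                resolution=float(data["resolution"]),
                max_mass=float(data["max_mass"]),
                min_count=data["min_count"].astype(np.uint8),
            )
        table.residue_bins = {
            t: table.bin_of(m) for t, m in vocab.masses.items()
        }
        return table


def vocabulary_hash(vocab: ResidueVocabulary) -> str:
    """Stable short hash of (token, mass) pairs, for cache keys."""
    payload = ";".join(f"{t}:{vocab.masses[t]:.6f}" for t in vocab.tokens)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_table(
    vocab: ResidueVocabulary,
    max_mass: float = 4000.0,
    resolution: float = DEFAULT_RESOLUTION,
    cache_dir: Optional[str | Path] = None,
) -> KnapsackTable:
    """Dynamic-programming closure of residue-sum reachability.

    Bin b is reachable iff b == 0 or b - bin(mass(r)) is reachable for
    some residue r. With ``cache_dir`` set, the table is loaded from /
    saved to a file keyed by (vocabulary hash, resolution, max_mass).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if max_mass <= max(vocab.masses.values()):
        raise ValueError("max_mass must exceed the largest residue mass")

    cache_path = None
    if cache_dir is not None:
        key = f"knapsack_{vocabulary_hash(vocab)}_{resolution:g}_{max_mass:g}.npz"
        cache_path = Path(cache_dir) / key
        if cache_path.exists():
            logger.info("loading knapsack table from %s", cache_path)
            return KnapsackTable.load(cache_path, vocab)

    n_bins = int(round(max_mass / resolution)) + 1
    residue_bins = {t: int(round(m / resolution)) for t, m in vocab.masses.items()}
    offsets = sorted(set(residue_bins.values()))
    min_count = np.full(n_bins, UNREACHABLE, dtype=np.uint8)
    min_count[0] = 0
    # Bins inside a block of width min(offsets) only depend on earlier
    # blocks, so each block updates with vectorized shifted minima.
    block = min(offsets)
    start = 1
    while start < n_bins:
        stop = min(start + block, n_bins)
        for off in offsets:
            src_lo = max(start - off, 0)
            dst_lo = src_lo + off
            if dst_lo >= stop:
                continue
            src = min_count[src_lo : stop - off]
            via = np.where(src < UNREACHABLE, src + 1, UNREACHABLE).astype(np.uint8)
            np.minimum(min_count[dst_lo:stop], via, out=min_count[dst_lo:stop])
        start = stop
    table = KnapsackTable(
        resolution=resolution,
        max_mass=max_mass,
        min_count=min_count,
        residue_bins=residue_bins,
    )
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        table.save(cache_path)
        logger.info("cached knapsack table at %s", cache_path)
    return table


def is_continuable(
    remaining_mass: float,
    table: KnapsackTable,
    tol_ppm: float = DEFAULT_PPM_TOL,
    precursor_mass: float = 0.0,
    max_residues: Optional[int] = None,
) -> bool:
    """Can the remaining mass budget be completed by some residue multiset?

    True iff a reachable bin lies within the absolute tolerance window
    (tol_ppm x precursor residue mass) around ``remaining_mass``. The
    window is widened by one bin on each side so discretization never
    produces a false "unreachable". Negative budgets beyond the window
    are dead ends. With ``max_residues`` set, only completions using at
    most that many residues count (the length-budget variant used inside
    beam search).
    """
    window = tol_ppm * 1e-6 * precursor_mass
    lo = int(np.floor((remaining_mass - window) / table.resolution))
    hi = int(np.ceil((remaining_mass + window) / table.resolution))
    if hi - lo > 2 * _EDGE_BINS:
        # pull the feasibility window in from the edges so a path flagged
        # feasible cannot land outside the exact tolerance at termination
        # (discretization drift is well under _EDGE_BINS for peptide
        # lengths <= 30); when the window is only a few bins wide, keep
        # the +-1-bin widening so reachability is never falsely denied
        lo += _EDGE_BINS
        hi -= _EDGE_BINS
    else:
        lo -= 1
        hi += 1
    if hi < 0 or lo >= table.n_bins:
        return False
    lo = max(lo, 0)
    hi = min(hi, table.n_bins - 1)
    counts = table.min_count[lo : hi + 1]
    bound = UNREACHABLE - 1 if max_residues is None else min(max_residues, UNREACHABLE - 1)
    return bool((counts <= bound).any())


@dataclass
class Prediction:
    """A decoded peptide for one spectrum (N->C residue order)."""

    spectrum_id: str
    peptide: Tuple[str, ...]
    per_residue_log_probs: Tuple[float, ...]
    log_prob: float  # sum of per-residue log-probabilities
    model_tag: str  # "ar" (autoregressive) or "diff" (diffusion-refined)
    precursor_ppm_error: float

    def __post_init__(self) -> None:
        self.peptide = tuple(self.peptide)
        self.per_residue_log_probs = tuple(float(x) for x in self.per_residue_log_probs)

    @property
    def confidence(self) -> float:
        return float(np.exp(self.log_prob))


@dataclass
class _BeamEntry:
    tokens: Tuple[int, ...]
    log_probs: Tuple[float, ...]
    score: float  # cumulative log-probability incl. nothing terminal yet
    remaining: float


def knapsack_beam_search(
    model,
    spectrum: Spectrum,
    table: KnapsackTable,
    beam_size: int = 5,
    tol_ppm: float = DEFAULT_PPM_TOL,
    max_len: Optional[int] = None,
    encoded=None,
) -> Optional[Prediction]:
    """Beam search over next-residue distributions with knapsack pruning.

    Every expansion whose remaining residue-mass budget fails
    :func:`is_continuable` is masked out; a sequence may terminate only
    when the assembled residue mass is within ``tol_ppm`` of the precursor
    residue mass. Terminal sequences are ranked by the sum of their
    per-residue log-probabilities, ties broken by lexicographic token
    order. Returns None only when no residue composition fits the window.
    """
    cfg = model.config
    vocab = model.vocab
    idx = model.token_index
    max_len = max_len or cfg.max_peptide_len
    target = spectrum.precursor_mass - WATER  # residue-sum budget
    if target <= 0:
        return None
    window = tol_ppm * 1e-6 * target

    residue_ids = np.array([idx[t] for t in vocab.tokens], dtype=np.int64)
    residue_masses = np.array([vocab.masses[t] for t in vocab.tokens])
    id2tok = {i: t for t, i in idx.items()}

    if encoded is None:
        encoded = model.encode_spectrum([spectrum])

    frontier: List[_BeamEntry] = [
        _BeamEntry(tokens=(), log_probs=(), score=0.0, remaining=target)
    ]
    completed: List[Tuple[float, Tuple[int, ...], _BeamEntry]] = []

    for step in range(max_len + 1):
        if not frontier:
            break
        # collect terminal sequences (mass window satisfied)
        for e in frontier:
            if abs(e.remaining) <= window and e.tokens:
                completed.append((e.score, e.tokens, e))
        if step == max_len:
            break
        prefixes = np.array([e.tokens for e in frontier], dtype=np.int64).reshape(
            len(frontier), -1
        )
        batch_enc = _tile_encoding(encoded, len(frontier))
        logits = model.next_token_logits(batch_enc, prefixes)
        logp = nn.log_softmax_np(logits, axis=-1)
        candidates: List[_BeamEntry] = []
        steps_left = max_len - step - 1  # residues that may still follow
        for e, row in zip(frontier, logp):
            rem = e.remaining - residue_masses
            for rid, r_rem in zip(residue_ids, rem):
                # feasible iff completable within the remaining length
                # budget; no valid <= max_len sequence is ever pruned
                if not is_continuable(r_rem, table, tol_ppm, target, steps_left):
                    continue
                candidates.append(
                    _BeamEntry(
                        tokens=e.tokens + (int(rid),),
                        log_probs=e.log_probs + (float(row[rid]),),
                        score=e.score + float(row[rid]),
                        remaining=float(r_rem),
                    )
                )
        candidates.sort(key=lambda c: (-c.score, c.tokens))
        frontier = candidates[:beam_size]

    if not completed:
        return None
    completed.sort(key=lambda c: (-c[0], c[1]))
    _, tokens, entry = completed[0]
    toks = [id2tok[i] for i in tokens]
    lps = list(entry.log_probs)
    if cfg.decode_direction == "rtl":
        toks = toks[::-1]
        lps = lps[::-1]
    residue_mass = float(np.sum([vocab.masses[t] for t in toks]))
    return Prediction(
        spectrum_id=spectrum.id,
        peptide=tuple(toks),
        per_residue_log_probs=tuple(lps),
        log_prob=float(sum(lps)),
        model_tag="ar",
        precursor_ppm_error=ppm_diff(residue_mass, target),
    )


def _tile_encoding(encoded, n: int):
    """Broadcast a single-spectrum encoding across a beam of size n."""
    from .model import EncodedSpectrum

    if encoded.memory.shape[0] == n:
        return encoded
    mem = nn.Tensor(np.repeat(encoded.memory.data, n, axis=0))
    pad = np.repeat(encoded.pad_mask, n, axis=0)
    masses = (
        np.repeat(encoded.precursor_masses, n)
        if encoded.precursor_masses is not None
        else None
    )
    prec = (
        nn.Tensor(np.repeat(encoded.precursor.data, n, axis=0))
        if encoded.precursor is not None
        else None
    )
    return EncodedSpectrum(
        memory=mem, pad_mask=pad, precursor=prec, precursor_masses=masses
    )
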