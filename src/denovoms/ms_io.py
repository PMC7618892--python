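"""Spectrum / PSM input-output, dataset filters, and leakage-free splits.

MGF and mzML parsing goes through :mod:`pyteomics`; the MGF writer emits a
fixed-format dialect so that files generated from a seed are byte-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import base64
import zlib

import numpy as np
import pandas as pd
from lxml import etree
from pyteomics import mgf as _mgf

from .chemistry import (
    ResidueVocabulary,
    mass_from_mz,
    mz_from_mass,
    parse_peptide,
    peptide_mass,
    ppm_diff,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "AnnotatedPSM",
    "SpectrumReader",
    "read_spectra",
    "write_mgf",
    "FilterStats",
    "filter_dataset",
    "split_dataset",
    "read_annotations",
    "write_annotations",
    "write_predictions",
    "read_predictions",
    "truncate_peaks",
]

PREDICTION_COLUMNS = [
    "spectrum_id",
    "peptide",
    "log_prob",
    "confidence",
    "model",
    "precursor_ppm_error",
]


@dataclass
class Spectrum:
    """One MS2 scan: peak arrays plus precursor metadata.

    Invariants (enforced at construction): equal-length, ascending m/z
    arrays with non-negative intensities, and at least one peak.
    """

    id: str
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float
    precursor_charge: int
    retention_time: Optional[float] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size < 1:
            raise ValueError("a spectrum must contain at least one peak")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(self.mz, kind="stable")
        if not np.all(np.diff(order) > 0):
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def precursor_mass(self) -> float:
        """Neutral precursor mass (Da), derived from m/z and charge."""
        return mass_from_mz(self.precursor_mz, self.precursor_charge)

    def normalized(self) -> "Spectrum":
        """Scale intensities to the base peak (max = 1.0)."""
        top = float(self.intensity.max())
        inten = self.intensity / top if top > 0 else self.intensity
        return Spectrum(
            id=self.id,
            mz=self.mz.copy(),
            intensity=inten,
            precursor_mz=self.precursor_mz,
            precursor_charge=self.precursor_charge,
            retention_time=self.retention_time,
        )


@dataclass
class AnnotatedPSM:
    """A spectrum paired with its ground-truth peptide (residue tokens)."""

    spectrum: Spectrum
    peptide: Tuple[str, ...]

    def __post_init__(self) -> None:
        self.peptide = tuple(self.peptide)

    @property
    def peptide_str(self) -> str:
        return "".join(self.peptide)


class SpectrumReader:
    """Iterable over spectra in an MGF/mzML file.

    Records lacking a precursor charge are skipped and counted in
    ``.skipped``; intensities are normalized to the base peak at ingestion.
    """

    def __init__(self, path: str | Path, format: Optional[str] = None):
        path = Path(path)
        if format is None:
            suffix = path.suffix.lower()
            format = {".mgf": "mgf", ".mzml": "mzml"}.get(suffix)
            if format is None:
                raise ValueError(f"cannot infer spectrum format from {path.name!r}")
        if format not in ("mgf", "mzml"):
            raise ValueError(f"unsupported format {format!r}")
        self.path = path
        self.format = format
        self.skipped = 0

    def __iter__(self) -> Iterator[Spectrum]:
        if self.format == "mgf":
            yield from self._iter_mgf()
        else:
            yield from self._iter_mzml()

    def _iter_mgf(self) -> Iterator[Spectrum]:
        with _mgf.read(str(self.path), use_index=False) as reader:
            for i, scan in enumerate(reader):
                params = scan.get("params", {})
                title = str(params.get("title", f"scan={i}"))
                charge = params.get("charge")
                pepmass = params.get("pepmass")
                if charge is None or pepmass is None:
                    self.skipped += 1
                    logger.warning("skipping MGF scan %r: missing CHARGE/PEPMASS", title)
                    continue
                rt = params.get("rtinseconds")
                try:
                    spec = Spectrum(
                        id=title,
                        mz=scan["m/z array"],
                        intensity=scan["intensity array"],
                        precursor_mz=float(pepmass[0]),
                        precursor_charge=int(charge[0]),
                        retention_time=float(rt) if rt is not None else None,
                    )
                except (ValueError, KeyError) as exc:
                    raise ValueError(f"malformed MGF scan {title!r}: {exc}") from exc
                yield spec.normalized()

    def _iter_mzml(self) -> Iterator[Spectrum]:
        # Minimal reader for the standard mzML dialect (PSI accessions for
        # ms level, selected ion, and the base64 binary arrays).
        ns = "{http://psi.hupo.org/ms/mzml}"
        for _, elem in etree.iterparse(str(self.path), tag=f"{ns}spectrum"):
            sid = elem.get("id", "")
            try:
                spec = self._parse_mzml_spectrum(elem, ns, sid)
            except (ValueError, KeyError, TypeError) as exc:
                raise ValueError(f"malformed mzML scan {sid!r}: {exc}") from exc
            finally:
                elem.clear()
            if spec is not None:
                yield spec.normalized()

    def _parse_mzml_spectrum(self, elem, ns: str, sid: str) -> Optional[Spectrum]:
        def accession(parent, acc):
            node = parent.find(f".//{ns}cvParam[@accession='{acc}']")
            return None if node is None else node.get("value")

        if accession(elem, "MS:1000511") != "2":  # ms level
            return None
        pre_mz = accession(elem, "MS:1000744")  # selected ion m/z
        charge = accession(elem, "MS:1000041")  # charge state
        if pre_mz is None or charge is None:
            self.skipped += 1
            logger.warning("skipping mzML scan %r: missing precursor info", sid)
            return None
        rt = accession(elem, "MS:1000016")  # scan start time (minutes)
        arrays: Dict[str, np.ndarray] = {}
        for bda in elem.findall(f".//{ns}binaryDataArray"):
            dtype = np.float64 if accession(bda, "MS:1000523") is not None else np.float32
            raw = base64.b64decode((bda.find(f"{ns}binary").text or "").encode())
            if accession(bda, "MS:1000574") is not None:  # zlib compression
                raw = zlib.decompress(raw)
            name = "mz" if accession(bda, "MS:1000514") is not None else (
                "intensity" if accession(bda, "MS:1000515") is not None else None
            )
            if name:
                arrays[name] = np.frombuffer(raw, dtype=dtype).astype(np.float64)
        if "mz" not in arrays or arrays["mz"].size == 0:
            self.skipped += 1
            return None
        return Spectrum(
            id=sid,
            mz=arrays["mz"],
            intensity=arrays.get("intensity", np.ones_like(arrays["mz"])),
            precursor_mz=float(pre_mz),
            precursor_charge=int(float(charge)),
            retention_time=float(rt) * 60.0 if rt is not None else None,
        )


def read_spectra(path: str | Path, format: Optional[str] = None) -> SpectrumReader:
    """Open an MGF or mzML file as a stream of :class:`Spectrum`."""
    return SpectrumReader(path, format)


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF with fixed numeric formatting (byte-stable)."""
    with open(path, "w") as fh:
        for spec in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={spec.id}\n")
            fh.write(f"PEPMASS={spec.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={spec.precursor_charge}+\n")
            if spec.retention_time is not None:
                fh.write(f"RTINSECONDS={spec.retention_time:.3f}\n")
            for mz, inten in zip(spec.mz, spec.intensity):
                fh.write(f"{mz:.6f} {inten:.6f}\n")
            fh.write("END IONS\n")


# ---------------------------------------------------------------------------
# dataset filters and splits
# ---------------------------------------------------------------------------


@dataclass
class FilterStats:
    kept: int = 0
    removed_length: int = 0
    removed_peaks: int = 0


def filter_dataset(
    psms: Iterable[AnnotatedPSM],
    max_len: int = 30,
    max_peaks: int = 800,
    stats: Optional[FilterStats] = None,
) -> List[AnnotatedPSM]:
    """Keep PSMs with peptide length <= max_len and peak count <= max_peaks.

    This is the training-set construction rule: offending records are
    removed (use :func:`truncate_peaks` at inference instead, where any
    spectrum must be handled).
    """
    stats = stats if stats is not None else FilterStats()
    kept: List[AnnotatedPSM] = []
    for psm in psms:
        if len(psm.peptide) > max_len:
            stats.removed_length += 1
        elif psm.spectrum.n_peaks > max_peaks:
            stats.removed_peaks += 1
        else:
            stats.kept += 1
            kept.append(psm)
    logger.info(
        "filter_dataset: kept %d, removed %d (length), %d (peaks)",
        stats.kept,
        stats.removed_length,
        stats.removed_peaks,
    )
    return kept


def truncate_peaks(spectrum: Spectrum, max_peaks: int = 800) -> Spectrum:
    """Keep the ``max_peaks`` most intense peaks (inference-side cap)."""
    if spectrum.n_peaks <= max_peaks:
        return spectrum
    top = np.argsort(spectrum.intensity, kind="stable")[-max_peaks:]
    top.sort()
    return Spectrum(
        id=spectrum.id,
        mz=spectrum.mz[top],
        intensity=spectrum.intensity[top],
        precursor_mz=spectrum.precursor_mz,
        precursor_charge=spectrum.precursor_charge,
        retention_time=spectrum.retention_time,
    )


def split_dataset(
    psms: Sequence[AnnotatedPSM],
    fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> Tuple[List[AnnotatedPSM], List[AnnotatedPSM], List[AnnotatedPSM]]:
    """Partition PSMs into train/validation/test over UNIQUE peptides.

    Every PSM of a given peptide lands in the same split, so no peptide
    sequence leaks between splits. Unique peptides are shuffled with the
    seed and sliced at the (rounded) fractions, giving exact split sizes.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    peptides = sorted({psm.peptide_str for psm in psms})
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(peptides))
    n = len(peptides)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    assignment: Dict[str, int] = {}
    for rank, idx in enumerate(order):
        split = 0 if rank < n_train else (1 if rank < n_train + n_val else 2)
        assignment[peptides[idx]] = split
    out: Tuple[List[AnnotatedPSM], ...] = ([], [], [])
    for psm in psms:
        out[assignment[psm.peptide_str]].append(psm)
    return out


def assert_no_peptide_overlap(*splits: Sequence[AnnotatedPSM]) -> None:
    """Raise if any peptide sequence occurs in more than one split.

    Also usable for cross-dataset leakage checks (e.g. a high-confidence
    train set against an all-confidence test set).
    """
    seen: Dict[str, int] = {}
    for i, split in enumerate(splits):
        for psm in split:
            j = seen.setdefault(psm.peptide_str, i)
            if j != i:
                raise AssertionError(
                    f"peptide {psm.peptide_str!r} occurs in splits {j} and {i}"
                )


# ---------------------------------------------------------------------------
# annotation and prediction tables
# ---------------------------------------------------------------------------


def write_annotations(psms: Iterable[AnnotatedPSM], path: str | Path) -> None:
    rows = [{"spectrum_id": p.spectrum.id, "peptide": p.peptide_str} for p in psms]
    pd.DataFrame(rows, columns=["spectrum_id", "peptide"]).to_csv(path, index=False)


def read_annotations(path: str | Path) -> Dict[str, Tuple[str, ...]]:
    """Annotation CSV -> {spectrum_id: peptide tokens}."""
    df = pd.read_csv(path, dtype={"spectrum_id": str, "peptide": str})
    return {
        row.spectrum_id: tuple(parse_peptide(row.peptide)) for row in df.itertuples()
    }


def pair_annotations(
    spectra: Iterable[Spectrum], annotations: Dict[str, Tuple[str, ...]]
) -> List[AnnotatedPSM]:
    """Join spectra with their annotations by spectrum id."""
    out = []
    for spec in spectra:
        if spec.id in annotations:
            out.append(AnnotatedPSM(spectrum=spec, peptide=annotations[spec.id]))
    return out


def write_predictions(predictions: Iterable, path: str | Path) -> None:
    """Write decoded peptides as the standard prediction CSV."""
    rows = []
    for p in predictions:
        rows.append(
            {
                "spectrum_id": p.spectrum_id,
                "peptide": "".join(p.peptide),
                "log_prob": f"{p.log_prob:.8f}",
                "confidence": f"{p.confidence:.8e}",
                "model": p.model_tag,
                "precursor_ppm_error": f"{p.precursor_ppm_error:.4f}",
            }
        )
    pd.DataFrame(rows, columns=PREDICTION_COLUMNS).to_csv(path, index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"spectrum_id": str, "peptide": str})
    missing = set(PREDICTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"prediction table missing columns: {sorted(missing)}")
    return df
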