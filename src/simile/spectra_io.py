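"""Reading, validating, canonicalizing and writing fragmentation spectra.

A :class:`FragmentationSpectrum` is a centroided peak list: fragment m/z
values (Thomson), optional intensities, the precursor m/z and an adduct
label.  Spectra are carried through the rest of the pipeline as sorted m/z
arrays; intensities are read and written for interoperability but the
similarity calculation itself consumes only m/z values.

Supported formats are MGF (Mascot generic format, read/write, parsed with
:mod:`pyteomics.mgf`) and MSP (NIST-style text libraries, read only).
"""

from __future__ import annotations

import io
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
from pyteomics import mgf as _pymgf
from pyteomics.auxiliary import PyteomicsError

from .errors import EmptySpectrumError, ParameterError, SpectrumFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentationSpectrum",
    "canonicalize",
    "read_mgf",
    "read_msp",
    "write_mgf",
]


@dataclass(frozen=True, eq=False)
class FragmentationSpectrum:
    """One centroided fragmentation spectrum.

    Parameters
    ----------
    spectrum_id
        Opaque identifier (MGF TITLE / MSP NAME, or a running index).
    precursor_mz
        Mass-to-charge of the selected precursor ion, Th; must be > 0.
    mz
        Fragment m/z values, Th.  Canonical spectra are strictly ascending
        with all values > 0; use :func:`canonicalize` to enforce this.
    intensity
        Optional abundances, same length as ``mz``, non-negative.
    adduct
        Ionization form label such as ``"[M+H]+"``.
    metadata
        Open key -> string map carried through unchanged.
    """

    spectrum_id: str
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray | None = None
    adduct: str | None = None
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        if mz.ndim != 1 or mz.size < 1:
            raise ParameterError("spectrum must contain at least one fragment m/z")
        object.__setattr__(self, "mz", mz)
        if self.intensity is not None:
            inten = np.asarray(self.intensity, dtype=float)
            if inten.shape != mz.shape:
                raise ParameterError(
                    f"intensity length {inten.size} != mz length {mz.size} "
                    f"for spectrum {self.spectrum_id!r}"
                )
            if np.any(inten < 0):
                raise ParameterError(f"negative intensity in spectrum {self.spectrum_id!r}")
            object.__setattr__(self, "intensity", inten)
        if not np.isfinite(self.precursor_mz) or self.precursor_mz <= 0:
            raise ParameterError(
                f"precursor m/z must be positive, got {self.precursor_mz!r}"
            )

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def is_canonical(self) -> bool:
        """True when m/z values are strictly ascending and all positive."""
        return bool(np.all(self.mz > 0) and np.all(np.diff(self.mz) > 0))

    def __eq__(self, other) -> bool:
        if not isinstance(other, FragmentationSpectrum):
            return NotImplemented
        same_intensity = (
            (self.intensity is None and other.intensity is None)
            or (
                self.intensity is not None
                and other.intensity is not None
                and np.array_equal(self.intensity, other.intensity)
            )
        )
        return (
            self.spectrum_id == other.spectrum_id
            and self.precursor_mz == other.precursor_mz
            and np.array_equal(self.mz, other.mz)
            and same_intensity
            and self.adduct == other.adduct
            and dict(self.metadata) == dict(other.metadata)
        )

    __hash__ = None


def canonicalize(
    spectrum: FragmentationSpectrum, merge_tolerance: float = 0.0
) -> FragmentationSpectrum:
    """Sort peaks ascending, drop nonpositive m/z and merge near-duplicates.

    Peaks whose consecutive gaps are smaller than ``merge_tolerance`` are
    merged into one centroid: intensities are summed and the merged m/z is
    the intensity-weighted mean (unweighted when intensities are absent).
    The default tolerance of 0 performs no merging; library spectra are
    used as-is.  Idempotent: merged centroids are at least
    ``merge_tolerance`` apart.
    """
    if merge_tolerance < 0:
        raise ParameterError("merge_tolerance must be >= 0")
    mz = spectrum.mz
    inten = spectrum.intensity
    keep = mz > 0
    mz = mz[keep]
    if inten is not None:
        inten = inten[keep]
    if mz.size == 0:
        raise EmptySpectrumError(
            f"no positive-m/z peaks left in spectrum {spectrum.spectrum_id!r}"
        )
    order = np.argsort(mz, kind="stable")
    mz = mz[order]
    if inten is not None:
        inten = inten[order]

    if merge_tolerance > 0 and mz.size > 1:
        # single-linkage clustering of consecutive gaps < tolerance
        cluster = np.concatenate([[0], np.cumsum(np.diff(mz) >= merge_tolerance)])
        n_clusters = cluster[-1] + 1
        if inten is not None:
            totals = np.bincount(cluster, weights=inten, minlength=n_clusters)
            # fall back to unweighted centroids for zero-intensity clusters
            weighted = np.bincount(cluster, weights=inten * mz, minlength=n_clusters)
            counts = np.bincount(cluster, minlength=n_clusters)
            plain = np.bincount(cluster, weights=mz, minlength=n_clusters) / counts
            with np.errstate(invalid="ignore"):
                centroids = np.where(totals > 0, weighted / np.where(totals > 0, totals, 1.0), plain)
            mz, inten = centroids, totals
        else:
            counts = np.bincount(cluster, minlength=n_clusters)
            mz = np.bincount(cluster, weights=mz, minlength=n_clusters) / counts
    else:
        # exact duplicates only merge when a positive tolerance is given;
        # sorting alone is sufficient for tolerance 0
        pass

    return FragmentationSpectrum(
        spectrum_id=spectrum.spectrum_id,
        precursor_mz=spectrum.precursor_mz,
        mz=mz,
        intensity=inten,
        adduct=spectrum.adduct,
        metadata=spectrum.metadata,
    )


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def _as_text(source: str | Path | IO) -> str:
    if isinstance(source, (str, Path)):
        return Path(source).read_text()
    data = source.read()
    if isinstance(data, bytes):
        data = data.decode("utf-8")
    return data


def _find_line(text: str, needle: str) -> int | None:
    for i, line in enumerate(text.splitlines(), start=1):
        if line.strip() == needle.strip():
            return i
    return None


def read_mgf(source: str | Path | IO, merge_tolerance: float = 0.0) -> list[FragmentationSpectrum]:
    """Parse an MGF stream or path into a list of canonical spectra.

    TITLE is used as the spectrum id when present, else a running index.
    Parameter keys are case-normalized to lowercase in ``metadata``.
    Malformed blocks (missing END IONS, unparsable peak lines) raise
    :class:`SpectrumFormatError` naming the offending line; an empty
    stream yields an empty list.
    """
    text = _as_text(source)
    if not text.strip():
        return []
    spectra: list[FragmentationSpectrum] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            entries = list(_pymgf.MGF(io.StringIO(text)))
    except PyteomicsError as exc:
        # pyteomics quotes the offending line (newline may appear as a
        # literal backslash-n in the repr); recover its number
        msg = str(exc)
        match = re.search(r"Line:(?:\\n|\n)(.+?)(?:\\n|\n|'|$)", msg)
        bad = match.group(1).strip() if match else ""
        raise SpectrumFormatError(
            f"unparsable MGF peak line {bad!r}", line=_find_line(text, bad)
        ) from exc
    for idx, entry in enumerate(entries):
        if entry is None:
            # pyteomics yields None for a BEGIN IONS block without END IONS
            last_begin = None
            for i, line in enumerate(text.splitlines(), start=1):
                if line.strip().upper() == "BEGIN IONS":
                    last_begin = i
            raise SpectrumFormatError(
                "MGF block missing END IONS", line=last_begin
            )
        params = entry.get("params", {})
        if "pepmass" not in params:
            raise SpectrumFormatError(f"MGF block {idx} missing PEPMASS")
        pepmass = params["pepmass"]
        precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
        title = params.get("title")
        metadata = {
            k: str(v) for k, v in params.items() if k not in ("pepmass", "charge")
        }
        mz = np.asarray(entry["m/z array"], dtype=float)
        if mz.size == 0:
            raise SpectrumFormatError(f"MGF block {idx} contains no peaks")
        inten = entry.get("intensity array")
        inten = np.asarray(inten, dtype=float) if inten is not None and len(inten) else None
        spec = FragmentationSpectrum(
            spectrum_id=str(title) if title is not None else str(idx),
            precursor_mz=precursor,
            mz=mz,
            intensity=inten,
            adduct=metadata.get("adduct"),
            metadata=metadata,
        )
        spectra.append(canonicalize(spec, merge_tolerance))
    return spectra


def write_mgf(spectra: Iterable[FragmentationSpectrum], sink: str | Path | IO) -> None:
    """Write spectra as MGF blocks; round-trips m/z to full precision."""
    entries = []
    for spec in spectra:
        params = {k: v for k, v in spec.metadata.items() if k != "title"}
        params["title"] = spec.spectrum_id
        params["pepmass"] = spec.precursor_mz
        if spec.adduct is not None:
            params["adduct"] = spec.adduct
        inten = spec.intensity
        entries.append(
            {
                "params": params,
                "m/z array": spec.mz,
                "intensity array": inten if inten is not None else np.zeros_like(spec.mz),
            }
        )
    if isinstance(sink, (str, Path)):
        with open(sink, "w") as fh:
            _pymgf.write(entries, fh)
    else:
        _pymgf.write(entries, sink)


# ---------------------------------------------------------------------------
# MSP
# ---------------------------------------------------------------------------

def read_msp(source: str | Path | IO, merge_tolerance: float = 0.0) -> list[FragmentationSpectrum]:
    """Parse a NIST-style MSP library into canonical spectra.

    Records follow the NAME / PRECURSORMZ / Num Peaks layout.  The declared
    peak count must match the number of parsed peak lines (format error
    otherwise); records without a precursor m/z are skipped with a logged
    warning.  This reader is strict by design so that library defects
    surface as errors rather than silently truncated spectra.
    """
    text = _as_text(source)
    spectra: list[FragmentationSpectrum] = []
    lines = text.splitlines()
    i = 0
    counter = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if ":" not in line:
            raise SpectrumFormatError(f"expected 'KEY: value', got {line!r}", line=i + 1)
        # one record: header fields until "Num Peaks", then that many peak lines
        fields: dict[str, str] = {}
        start_line = i + 1
        n_peaks = None
        while i < len(lines):
            line = lines[i].strip()
            if not line:
                break
            key, _, value = line.partition(":")
            key_norm = key.strip().lower().replace(" ", "_")
            fields[key.strip()] = value.strip()
            i += 1
            if key_norm == "num_peaks":
                try:
                    n_peaks = int(value.strip())
                except ValueError:
                    raise SpectrumFormatError(
                        f"bad Num Peaks value {value.strip()!r}", line=i
                    ) from None
                break
        if n_peaks is None:
            raise SpectrumFormatError(
                "MSP record missing 'Num Peaks'", line=start_line
            )
        peaks: list[tuple[float, float | None]] = []
        while i < len(lines) and lines[i].strip():
            parts = lines[i].replace(";", " ").split()
            try:
                mz_val = float(parts[0])
                inten_val = float(parts[1]) if len(parts) > 1 else None
            except (ValueError, IndexError):
                raise SpectrumFormatError(
                    f"unparsable MSP peak line {lines[i].strip()!r}", line=i + 1
                ) from None
            peaks.append((mz_val, inten_val))
            i += 1
        if len(peaks) != n_peaks:
            raise SpectrumFormatError(
                f"MSP record declares {n_peaks} peaks but has {len(peaks)}",
                line=start_line,
            )
        precursor_key = next(
            (k for k in fields if k.lower() in ("precursormz", "precursor_mz")), None
        )
        name = fields.get("NAME") or fields.get("Name") or str(counter)
        counter += 1
        if precursor_key is None:
            logger.warning("skipping MSP record %r: no PRECURSORMZ", name)
            continue
        mz = np.array([p[0] for p in peaks])
        intens = (
            np.array([p[1] for p in peaks])
            if all(p[1] is not None for p in peaks)
            else None
        )
        metadata = {
            k: v
            for k, v in fields.items()
            if k.lower() not in ("name", "precursormz", "precursor_mz", "num peaks")
        }
        spec = FragmentationSpectrum(
            spectrum_id=name,
            precursor_mz=float(fields[precursor_key]),
            mz=mz,
            intensity=intens,
            adduct=metadata.get("Precursor_type") or metadata.get("PRECURSORTYPE"),
            metadata=metadata,
        )
        spectra.append(canonicalize(spec, merge_tolerance))
    return spectra
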