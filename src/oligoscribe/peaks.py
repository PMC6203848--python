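"""Observed MS/MS spectra as peak lists.

A :class:`PeakList` is the minimal view of a tandem-MS spectrum the reader
needs: (m/z, intensity) pairs sorted by m/z, the precursor m/z, and an
optional noise-floor estimate for signal-to-noise filtering.  Ingestion
from MGF (via pyteomics) and from plain two-column CSV is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pyteomics import mgf as _mgf

from .errors import FormatError


@dataclass(frozen=True)
class PeakList:
    """An MS/MS spectrum: sorted peaks plus precursor m/z.

    ``noise_level`` (same arbitrary units as ``intensity``) is the noise
    floor used for S/N filtering; when absent, readers estimate it as the
    median peak intensity.
    """

    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    noise_level: float | None = None
    title: str = field(default="", compare=False)

    def __init__(self, mz, intensity, precursor_mz=None, noise_level=None, title=""):
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        if mz.shape != intensity.shape or mz.ndim != 1:
            raise FormatError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and mz.min() <= 0:
            raise FormatError("all m/z values must be positive")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", intensity[order])
        object.__setattr__(self, "precursor_mz",
                           None if precursor_mz is None else float(precursor_mz))
        object.__setattr__(self, "noise_level",
                           None if noise_level is None else float(noise_level))
        object.__setattr__(self, "title", title)

    def __len__(self) -> int:
        return int(self.mz.size)

    def __eq__(self, other):
        if not isinstance(other, PeakList):
            return NotImplemented
        return (
            np.array_equal(self.mz, other.mz)
            and np.array_equal(self.intensity, other.intensity)
            and self.precursor_mz == other.precursor_mz
            and self.noise_level == other.noise_level
        )

    # ---- MGF ------------------------------------------------------------
    def to_mgf(self, path) -> None:
        params = {}
        if self.title:
            params["title"] = self.title
        if self.precursor_mz is not None:
            params["pepmass"] = self.precursor_mz
        if self.noise_level is not None:
            params["noiselevel"] = self.noise_level
        spectrum = {
            "m/z array": self.mz,
            "intensity array": self.intensity,
            "params": params,
        }
        _mgf.write([spectrum], output=str(path), file_mode="w")

    @classmethod
    def from_mgf(cls, path, *, precursor_mz=None) -> "PeakList":
        """Read the first spectrum of an MGF file.

        ``precursor_mz`` overrides the file's PEPMASS when given.
        """
        with _mgf.MGF(str(path)) as reader:
            try:
                spectrum = next(iter(reader))
            except StopIteration:
                raise FormatError(f"{path}: no spectrum found") from None
        params = spectrum.get("params", {})
        if precursor_mz is None:
            pepmass = params.get("pepmass")
            if pepmass is not None:
                precursor_mz = pepmass[0] if isinstance(pepmass, tuple) else pepmass
        noise = params.get("noiselevel")
        return cls(
            spectrum["m/z array"],
            spectrum["intensity array"],
            precursor_mz=precursor_mz,
            noise_level=None if noise is None else float(noise),
            title=str(params.get("title", "")),
        )

    # ---- two-column CSV -------------------------------------------------
    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("mz,intensity\n")
            for m, i in zip(self.mz, self.intensity):
                fh.write(f"{float(m)!r},{float(i)!r}\n")

    @classmethod
    def from_csv(cls, path, *, precursor_mz=None, noise_level=None) -> "PeakList":
        """Read a two-column m/z,intensity CSV (header optional).

        CSV carries no precursor; supply it via ``precursor_mz``.
        """
        rows = []
        with open(path, encoding="utf-8") as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split(",")
                if len(parts) != 2:
                    raise FormatError(f"{path}:{ln}: expected two comma-separated columns")
                if ln == 1 and not _is_float(parts[0]):
                    continue  # header
                try:
                    rows.append((float(parts[0]), float(parts[1])))
                except ValueError:
                    raise FormatError(f"{path}:{ln}: non-numeric row {line!r}") from None
        mz = [r[0] for r in rows]
        inten = [r[1] for r in rows]
        return cls(mz, inten, precursor_mz=precursor_mz, noise_level=noise_level)


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
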