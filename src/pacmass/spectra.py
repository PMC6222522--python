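"""MS/MS peak-list I/O: MGF (via pyteomics) and two-column text."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from pyteomics import mgf

__all__ = ["Spectrum", "read_mgf", "write_mgf", "read_peaklist", "write_peaklist"]


@dataclass
class Spectrum:
    """A tandem spectrum: peak list plus precursor metadata."""

    peaks: list[tuple[float, float]]  # (m/z, intensity)
    precursor_mz: Optional[float] = None
    charge: int = 1  # magnitude; negative polarity implied
    title: str = ""
    params: dict = field(default_factory=dict)


def read_mgf(path) -> list[Spectrum]:
    """Read every spectrum from an MGF file (negative-mode charges)."""
    spectra = []
    with mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry.get("params", {})
            pepmass = params.get("pepmass", (None,))
            charge_list = params.get("charge")
            charge = abs(int(charge_list[0])) if charge_list else 1
            spectra.append(
                Spectrum(
                    peaks=list(zip(entry["m/z array"].tolist(), entry["intensity array"].tolist())),
                    precursor_mz=pepmass[0],
                    charge=charge,
                    title=str(params.get("title", "")),
                    params=dict(params),
                )
            )
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    entries = []
    for s in spectra:
        mzs, intensities = zip(*s.peaks) if s.peaks else ((), ())
        params = {"title": s.title, "charge": [-abs(s.charge)]}
        if s.precursor_mz is not None:
            params["pepmass"] = s.precursor_mz
        entries.append(
            {"m/z array": list(mzs), "intensity array": list(intensities), "params": params}
        )
    mgf.write(entries, str(path), file_mode="w")


def read_peaklist(path) -> Spectrum:
    """Read a headerless two-column (m/z, intensity) text file.

    Whitespace-, comma- or tab-delimited; blank lines and ``#`` comments
    are skipped.  A single bare m/z column gets unit intensities.
    """
    peaks: list[tuple[float, float]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.replace(",", " ").split()
            try:
                mz = float(parts[0])
                intensity = float(parts[1]) if len(parts) > 1 else 1.0
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: cannot parse peak {text!r}") from exc
            peaks.append((mz, intensity))
    return Spectrum(peaks=peaks)


def write_peaklist(spectrum: Spectrum, path) -> None:
    with open(path, "w") as handle:
        for mz, intensity in spectrum.peaks:
            handle.write(f"{mz:.6f}\t{intensity:.3f}\n")
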