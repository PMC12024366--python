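"""Spectrum and sample-table I/O.

A :class:`Spectrum` holds one ATR-FTIR absorbance trace on a strictly
monotonic wavenumber grid.  Instrument convention is descending wavenumber
(4000 -> 700 cm-1); spectra read in ascending order are re-oriented on
ingest.  Supported on-disk formats are two-column CSV and JCAMP-DX
(AFFN-encoded ``XYDATA (X++(Y..Y))`` and ``XYPOINTS (XY..XY)`` forms).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Wavenumber range (cm-1) required for full-pipeline use.
FULL_RANGE = (700.0, 4000.0)

SPECIES = (
    "Crocuta crocuta",
    "Hyaena hyaena",
    "Parahyaena brunnea",
    "Proteles cristatus",
)


class SpectrumFormatError(ValueError):
    """A spectrum file could not be parsed in the requested dialect."""


class SpectrumValidationError(ValueError):
    """Parsed data violate the Spectrum invariants."""


@dataclass
class Spectrum:
    """One absorbance spectrum on a strictly monotonic wavenumber grid.

    Parameters
    ----------
    wavenumbers
        Grid in cm-1.  Accepted in either orientation, stored descending.
    absorbance
        Unitless absorbance (AU), same length as ``wavenumbers``.
    sample_id
        Identifier of the physical sample (e.g. ``CC-kip5``).
    replicate
        Index of the analysed fragment (four fragments per coprolite is
        the acquisition default).
    provenance
        Free-text processing history.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""
    replicate: int = 0
    provenance: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if w.ndim != 1 or a.ndim != 1 or w.size != a.size:
            raise SpectrumValidationError(
                f"wavenumbers ({w.size}) and absorbance ({a.size}) must be "
                "1-D arrays of equal length"
            )
        if w.size < 2:
            raise SpectrumValidationError("a spectrum needs at least 2 points")
        if not (np.isfinite(w).all() and np.isfinite(a).all()):
            raise SpectrumValidationError("missing or non-finite values")
        dw = np.diff(w)
        if np.any(dw == 0):
            dup = w[:-1][dw == 0][0]
            raise SpectrumValidationError(f"duplicated wavenumber {dup:g} cm-1")
        if not (np.all(dw > 0) or np.all(dw < 0)):
            raise SpectrumValidationError("wavenumber grid is not monotonic")
        if dw[0] > 0:  # ascending on input -> store descending
            w = w[::-1].copy()
            a = a[::-1].copy()
        if self.replicate < 0:
            raise SpectrumValidationError("replicate index must be >= 0")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "absorbance", a)
        if w[-1] > FULL_RANGE[0] or w[0] < FULL_RANGE[1]:
            logger.warning(
                "spectrum %s covers %.0f-%.0f cm-1, narrower than the "
                "%.0f-%.0f cm-1 range needed for the full pipeline",
                self.sample_id or "<unnamed>", w[-1], w[0], *FULL_RANGE,
            )

    # -- convenience -------------------------------------------------------

    @property
    def wmin(self) -> float:
        return float(self.wavenumbers[-1])

    @property
    def wmax(self) -> float:
        return float(self.wavenumbers[0])

    def interp(self, at: np.ndarray | float) -> np.ndarray:
        """Linear interpolation of absorbance at wavenumber(s) ``at``."""
        # np.interp requires ascending abscissae
        return np.interp(at, self.wavenumbers[::-1], self.absorbance[::-1])

    def ascending(self) -> tuple[np.ndarray, np.ndarray]:
        """(wavenumbers, absorbance) in ascending wavenumber order."""
        return self.wavenumbers[::-1], self.absorbance[::-1]

    def with_absorbance(self, a: np.ndarray, note: str = "") -> "Spectrum":
        prov = f"{self.provenance}; {note}" if note and self.provenance else (note or self.provenance)
        return Spectrum(self.wavenumbers.copy(), np.asarray(a, float),
                        self.sample_id, self.replicate, prov)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _infer_dialect(path: Path) -> str:
    if path.suffix.lower() in {".jdx", ".dx", ".jcm", ".jcamp"}:
        return "jcamp"
    return "csv"


def read_spectrum(path: str | Path, dialect: str | None = None, *,
                  sample_id: str = "", replicate: int = 0) -> Spectrum:
    """Read one spectrum from ``path``.

    ``dialect`` is ``"jcamp"`` or ``"csv"``; inferred from the file suffix
    when omitted.  CSV files hold two columns (wavenumber, absorbance) with
    an optional header row.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "csv":
        w, a = _read_csv(path)
    elif dialect == "jcamp":
        w, a = _read_jcamp(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected jcamp or csv)")
    sid = sample_id or path.stem
    return Spectrum(w, a, sample_id=sid, replicate=replicate,
                    provenance=f"read from {path.name} ({dialect})")


def _read_csv(path: Path) -> tuple[np.ndarray, np.ndarray]:
    ws: list[float] = []
    ab: list[float] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or not "".join(row).strip():
                continue
            if len(row) < 2:
                raise SpectrumFormatError(
                    f"{path.name}:{lineno}: expected 2 columns, got {len(row)}")
            try:
                ws.append(float(row[0]))
                ab.append(float(row[1]))
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise SpectrumFormatError(
                    f"{path.name}:{lineno}: non-numeric row {row!r}") from None
    if len(ws) < 2:
        raise SpectrumFormatError(f"{path.name}: fewer than 2 data rows")
    return np.array(ws), np.array(ab)


_NUM = r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?"


def _read_jcamp(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal JCAMP-DX reader for AFFN XYDATA/XYPOINTS blocks."""
    meta: dict[str, str] = {}
    data_lines: list[str] = []
    mode = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("$$")[0].rstrip()
            if not line.strip():
                continue
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                val = val.strip()
                if key == "XYDATA":
                    mode = "xydata"
                elif key == "XYPOINTS":
                    mode = "xypoints"
                elif key == "END":
                    break
                else:
                    meta[key] = val
            elif mode in ("xydata", "xypoints"):
                data_lines.append(line)
            # other free text before the data block is ignored
    if mode is None:
        raise SpectrumFormatError(f"{path.name}: no XYDATA/XYPOINTS block found")
    xf = float(meta.get("XFACTOR", 1.0))
    yf = float(meta.get("YFACTOR", 1.0))
    ws: list[float] = []
    ab: list[float] = []
    if mode == "xypoints":
        for line in data_lines:
            nums = re.findall(_NUM, line)
            if len(nums) % 2:
                raise SpectrumFormatError(
                    f"{path.name}: odd value count in XYPOINTS line {line!r}")
            vals = [float(v) for v in nums]
            ws.extend(v * xf for v in vals[0::2])
            ab.extend(v * yf for v in vals[1::2])
    else:  # (X++(Y..Y))
        for line in data_lines:
            nums = re.findall(_NUM, line)
            if len(nums) < 2:
                raise SpectrumFormatError(
                    f"{path.name}: malformed XYDATA line {line!r}")
            x0 = float(nums[0]) * xf
            ys = [float(v) * yf for v in nums[1:]]
            if len(data_lines) > 1 or "DELTAX" in meta or "LASTX" in meta:
                if "DELTAX" in meta:
                    dx = float(meta["DELTAX"])
                else:
                    npts = int(float(meta["NPOINTS"]))
                    dx = (float(meta["LASTX"]) - float(meta["FIRSTX"])) / (npts - 1)
                ws.extend(x0 + i * dx for i in range(len(ys)))
            else:
                raise SpectrumFormatError(
                    f"{path.name}: XYDATA needs DELTAX or FIRSTX/LASTX/NPOINTS")
            ab.extend(ys)
    if "NPOINTS" in meta and int(float(meta["NPOINTS"])) != len(ws):
        raise SpectrumFormatError(
            f"{path.name}: NPOINTS={meta['NPOINTS']} but {len(ws)} points read")
    return np.array(ws), np.array(ab)


def write_spectrum(s: Spectrum, path: str | Path, dialect: str | None = None) -> Path:
    """Write ``s`` to ``path`` in the given dialect (inferred from suffix)."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "csv":
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["wavenumber_cm-1", "absorbance"])
            for w, a in zip(s.wavenumbers, s.absorbance):
                wr.writerow([f"{w:.10g}", f"{a:.12g}"])
    elif dialect == "jcamp":
        with open(path, "w") as fh:
            fh.write(f"##TITLE={s.sample_id or path.stem}\n")
            fh.write("##JCAMP-DX=4.24\n##DATA TYPE=INFRARED SPECTRUM\n")
            fh.write("##XUNITS=1/CM\n##YUNITS=ABSORBANCE\n")
            fh.write("##XFACTOR=1\n##YFACTOR=1\n")
            fh.write(f"##FIRSTX={s.wavenumbers[0]:.10g}\n")
            fh.write(f"##LASTX={s.wavenumbers[-1]:.10g}\n")
            fh.write(f"##NPOINTS={s.wavenumbers.size}\n")
            fh.write("##XYPOINTS=(XY..XY)\n")
            for w, a in zip(s.wavenumbers, s.absorbance):
                fh.write(f"{w:.10g}, {a:.12g}\n")
            fh.write("##END=\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


# ---------------------------------------------------------------------------
# replicate averaging
# ---------------------------------------------------------------------------

def average_replicates(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate spectra of one sample.

    Grids may differ; all spectra are resampled by linear interpolation
    onto the intersection of their ranges at the coarsest grid step.
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 replicate spectra to average")
    ids = {s.sample_id for s in spectra}
    if len(ids) != 1:
        raise ValueError(f"mixed sample_ids in replicate set: {sorted(ids)}")
    lo = max(s.wmin for s in spectra)
    hi = min(s.wmax for s in spectra)
    if lo >= hi:
        raise ValueError("replicate spectra have disjoint wavenumber ranges")
    step = max(float(np.median(np.abs(np.diff(s.wavenumbers)))) for s in spectra)
    grid = np.arange(hi, lo - 0.5 * step, -step)  # descending
    mean = np.mean([s.interp(grid) for s in spectra], axis=0)
    return Spectrum(grid, mean, sample_id=spectra[0].sample_id,
                    provenance=f"mean of {len(spectra)} replicates")


# ---------------------------------------------------------------------------
# sample metadata table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleRecord:
    """Provenance of one coprolite sample (one row of the metadata table)."""

    species: str
    country: str
    region: str
    code: str
    length_mm: float | None = None
    width_mm: float | None = None
    context: str = "isolated"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(
                f"unknown species {self.species!r}; allowed: {', '.join(SPECIES)}")
        for v, name in ((self.length_mm, "length_mm"), (self.width_mm, "width_mm")):
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.context not in ("isolated", "latrine"):
            raise ValueError(f"context must be isolated|latrine, got {self.context!r}")

    @property
    def max_size_mm(self) -> float | None:
        sizes = [v for v in (self.length_mm, self.width_mm) if v is not None]
        return max(sizes) if sizes else None


def _parse_size(text: str) -> tuple[float | None, float | None, str]:
    """Parse an 'L x ep' size string; non-numeric entries become absent."""
    text = text.strip()
    if not text or text == "-":
        return None, None, ""
    if "x" in text:
        left, _, right = text.partition("x")

        def num(tok: str) -> float | None:
            tok = tok.strip()
            try:
                return float(tok)
            except ValueError:
                return None

        length, width = num(left), num(right)
        if length is not None or width is not None:
            return length, width, ""
    return None, None, text  # e.g. "small specimen"


def read_sample_table(path: str | Path | None = None) -> list[SampleRecord]:
    """Read the sample metadata table (the packaged hyaenid set by default)."""
    if path is None:
        ref = resources.files("coprofir.data") / "samples_hyaenidae.csv"
        with resources.as_file(ref) as p:
            return read_sample_table(p)
    records: list[SampleRecord] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            length, width, raw = _parse_size(row.get("size_mm", ""))
            prov = f"size noted as {raw!r}" if raw else ""
            records.append(SampleRecord(
                species=row["species"].strip(),
                country=row.get("country", "").strip(),
                region=row.get("region", "").strip(),
                code=row["code"].strip(),
                length_mm=length, width_mm=width,
                context=row.get("context", "isolated").strip(),
                provenance=prov,
            ))
    codes = [r.code for r in records]
    if len(set(codes)) != len(codes):
        dup = sorted({c for c in codes if codes.count(c) > 1})
        raise ValueError(f"duplicate sample codes: {dup}")
    return records
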