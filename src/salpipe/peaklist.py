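"""Peak-list readers/writers (MGF and CSV dialects) and report formatting.

Two dialects are supported: Mascot generic format (BEGIN IONS / PEPMASS /
CHARGE blocks, every block treated as a fragmentation spectrum) and a
4-column CSV (``level,precursor_mz,mz,intensity``) that can carry MS1/MS2/MS3
together.  m/z values are parsed at full printed precision; report writers
print m/z to 4 decimals and ppm to 3 decimals with stable key ordering, so
byte-identical inputs give byte-identical reports.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path

from .annotate import Peak, Spectrum

__all__ = ["read_peaklist", "write_peaklist", "write_report", "fmt_mz", "fmt_ppm"]


def fmt_mz(value: float) -> float:
    return round(float(value), 4)


def fmt_ppm(value: float) -> float:
    return round(float(value), 3)


def _detect_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mgf":
        return "mgf"
    if suffix in (".csv", ".tsv", ".txt"):
        return "csv"
    raise ValueError(f"cannot infer peak-list dialect from {path.name!r}")


def _read_mgf(path: Path) -> list[Spectrum]:
    from pyteomics import mgf

    spectra = []
    with mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            pepmass = params.get("pepmass")
            precursor = float(pepmass[0]) if pepmass else None
            charge = params.get("charge")
            polarity = "-"
            if charge:
                polarity = "-" if int(charge[0]) < 0 else "+"
            peaks = tuple(
                Peak(float(mz), float(it))
                for mz, it in zip(entry["m/z array"], entry["intensity array"])
            )
            level = int(params.get("mslevel", 2))
            spectra.append(
                Spectrum(level=level, peaks=peaks, precursor_mz=precursor,
                         polarity=polarity)
            )
    return spectra


def _read_csv(path: Path) -> list[Spectrum]:
    groups: dict[tuple, list[Peak]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"level", "precursor_mz", "mz", "intensity"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"CSV peak list needs columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                level = int(row["level"])
                precursor = row["precursor_mz"].strip()
                precursor = float(precursor) if precursor else None
                peak = Peak(float(row["mz"]), float(row["intensity"] or 0.0))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"malformed CSV peak row at line {lineno}: {exc}")
            groups.setdefault((level, precursor), []).append(peak)
    return [
        Spectrum(level=level, peaks=tuple(peaks), precursor_mz=precursor)
        for (level, precursor), peaks in groups.items()
    ]


def read_peaklist(path, dialect: str | None = None) -> list[Spectrum]:
    """Read spectra from an MGF or CSV file; peaks come back m/z-sorted."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _detect_dialect(path)
    if dialect not in ("mgf", "csv"):
        raise ValueError(f"unknown peak-list dialect {dialect!r}")
    spectra = _read_mgf(path) if dialect == "mgf" else _read_csv(path)
    if not spectra:
        warnings.warn(f"empty peak list: {path}")
    return spectra


def write_peaklist(spectra, path, dialect: str | None = None) -> None:
    path = Path(path)
    dialect = dialect or _detect_dialect(path)
    if dialect == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["level", "precursor_mz", "mz", "intensity"])
            for s in spectra:
                prec = "" if s.precursor_mz is None else repr(s.precursor_mz)
                for p in s.peaks:
                    writer.writerow([s.level, prec, repr(p.mz), repr(p.intensity)])
    elif dialect == "mgf":
        with open(path, "w") as fh:
            for s in spectra:
                fh.write("BEGIN IONS\n")
                if s.precursor_mz is not None:
                    fh.write(f"PEPMASS={s.precursor_mz!r}\n")
                fh.write(f"CHARGE=1{'-' if s.polarity == '-' else '+'}\n")
                fh.write(f"MSLEVEL={s.level}\n")
                for p in s.peaks:
                    fh.write(f"{p.mz!r} {p.intensity!r}\n")
                fh.write("END IONS\n")
    else:
        raise ValueError(f"unknown peak-list dialect {dialect!r}")


def write_report(payload: dict, path) -> None:
    """Schema-versioned JSON report with deterministic formatting."""
    document = {"schema_version": 1, **payload}
    with open(path, "w") as fh:
        json.dump(document, fh, indent=2, sort_keys=True, default=_coerce)
        fh.write("\n")


def _coerce(obj):
    import dataclasses

    import numpy as np

    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialise {type(obj)!r}")
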