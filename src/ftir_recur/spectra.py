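"""Core domain types and I/O for ATR-FTIR spectra.

A :class:`Spectrum` is one absorbance trace over a wavenumber grid
(cm^-1, stored ascending); a :class:`SpectraSet` is a collection sharing
one grid, with per-spectrum metadata (patient, replicate, acquisition
batch, QC flag, cystoscopy label).

Supported on-disk formats are open text dialects:

* ``csv_wide``  — first column ``sample_id``, remaining headers numeric
  wavenumbers, one row per spectrum.
* ``csv_long``  — columns ``sample_id, wavenumber, absorbance``.
* ``jcampdx``   — JCAMP-DX 4.24 ``##XYDATA=(X++(Y..Y))``, one spectrum
  per file (a directory of files for a set).

Metadata travels in a sidecar CSV with columns
``sample_id, patient_id, replicate_index, batch_id, is_qc, label``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectrumMeta",
    "SpectraSet",
    "FormatError",
    "IntegrityError",
    "collapse_labels",
    "read_spectra",
    "write_spectra",
    "regrid",
]

#: Cystoscopy label vocabulary after collapsing to the binary response.
LABELS = ("free", "recurrence", "unknown")

#: Raw cystoscopy outcome categories before collapsing.
RAW_LABELS = ("free", "hyperplasia", "inflammation", "recurrence")


class FormatError(ValueError):
    """A file does not parse under the named dialect."""


class IntegrityError(ValueError):
    """Data violate a domain invariant (duplicates, non-finite values...)."""


@dataclass(frozen=True)
class SpectrumMeta:
    sample_id: str
    patient_id: str
    replicate_index: int
    batch_id: str
    is_qc: bool = False
    label: str = "unknown"

    def __post_init__(self):
        if self.replicate_index < 1:
            raise IntegrityError(
                f"replicate_index must be >= 1, got {self.replicate_index} "
                f"for sample {self.sample_id!r}"
            )
        if self.label not in LABELS:
            raise IntegrityError(
                f"label must be one of {LABELS}, got {self.label!r}"
            )
        if self.is_qc and self.label != "unknown":
            raise IntegrityError(
                f"QC spectrum {self.sample_id!r} must carry label='unknown'"
            )


@dataclass
class Spectrum:
    """One absorbance trace on a strictly ascending wavenumber grid."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: SpectrumMeta

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.ndim != 1 or self.absorbance.ndim != 1:
            raise IntegrityError("wavenumbers and absorbance must be 1-D")
        if len(self.wavenumbers) != len(self.absorbance):
            raise IntegrityError(
                f"grid/absorbance length mismatch for {self.meta.sample_id!r}: "
                f"{len(self.wavenumbers)} vs {len(self.absorbance)}"
            )
        if len(self.wavenumbers) and np.any(np.diff(self.wavenumbers) <= 0):
            raise IntegrityError(
                f"wavenumbers must be strictly increasing ({self.meta.sample_id!r})"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise IntegrityError(
                f"non-finite absorbance in spectrum {self.meta.sample_id!r}"
            )

    def with_values(self, wavenumbers, absorbance) -> "Spectrum":
        return Spectrum(np.asarray(wavenumbers, float),
                        np.asarray(absorbance, float), self.meta)


@dataclass
class SpectraSet:
    """Spectra sharing a single wavenumber grid, plus a provenance log."""

    spectra: list
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        if self.spectra:
            grid = self.spectra[0].wavenumbers
            for s in self.spectra[1:]:
                if len(s.wavenumbers) != len(grid) or not np.allclose(
                    s.wavenumbers, grid, rtol=0, atol=1e-9
                ):
                    raise IntegrityError(
                        f"spectrum {s.meta.sample_id!r} is on a different grid; "
                        "use regrid() explicitly if resampling is intended"
                    )
        seen = {}
        for s in self.spectra:
            key = (s.meta.patient_id, s.meta.replicate_index, s.meta.batch_id)
            if key in seen:
                raise IntegrityError(
                    f"duplicate (patient, replicate, batch) {key}: samples "
                    f"{seen[key]!r} and {s.meta.sample_id!r}"
                )
            seen[key] = s.meta.sample_id
        labels_by_patient = {}
        for s in self.spectra:
            if s.meta.label == "unknown":
                continue
            prev = labels_by_patient.setdefault(s.meta.patient_id, s.meta.label)
            if prev != s.meta.label:
                raise IntegrityError(
                    f"patient {s.meta.patient_id!r} carries conflicting labels "
                    f"{prev!r} and {s.meta.label!r}"
                )

    def __len__(self):
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def wavenumbers(self) -> np.ndarray:
        if not self.spectra:
            return np.empty(0)
        return self.spectra[0].wavenumbers

    @property
    def sample_ids(self) -> list:
        return [s.meta.sample_id for s in self.spectra]

    def to_matrix(self) -> np.ndarray:
        """Spectra stacked as a (n_spectra, n_channels) array."""
        if not self.spectra:
            return np.empty((0, 0))
        return np.vstack([s.absorbance for s in self.spectra])

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": s.meta.sample_id,
                    "patient_id": s.meta.patient_id,
                    "replicate_index": s.meta.replicate_index,
                    "batch_id": s.meta.batch_id,
                    "is_qc": s.meta.is_qc,
                    "label": s.meta.label,
                }
                for s in self.spectra
            ]
        )

    def subset(self, keep) -> "SpectraSet":
        """New set with the spectra whose sample_id is in ``keep``."""
        keep = set(keep)
        return SpectraSet(
            [s for s in self.spectra if s.meta.sample_id in keep],
            provenance=list(self.provenance),
        )

    def without_qc(self) -> "SpectraSet":
        return SpectraSet(
            [s for s in self.spectra if not s.meta.is_qc],
            provenance=list(self.provenance),
        )

    def log(self, message: str) -> None:
        self.provenance.append(message)


def collapse_labels(raw_label: str) -> str:
    """Collapse the four cystoscopy outcomes to the binary response.

    ``recurrence`` stays ``recurrence``; free, hyperplasia and
    inflammation all collapse to ``free`` (the NMIBC-free group).
    Idempotent on its own output alphabet.
    """
    if raw_label == "recurrence":
        return "recurrence"
    if raw_label in ("free", "hyperplasia", "inflammation"):
        return "free"
    raise IntegrityError(
        f"unknown cystoscopy category {raw_label!r}; expected one of {RAW_LABELS}"
    )


def regrid(spectrum: Spectrum, target_grid) -> Spectrum:
    """Linear interpolation onto ``target_grid``. Never applied implicitly."""
    target = np.asarray(target_grid, dtype=float)
    if target.min() < spectrum.wavenumbers.min() - 1e-9 or target.max() > (
        spectrum.wavenumbers.max() + 1e-9
    ):
        raise IntegrityError(
            f"target grid extends outside the measured range for "
            f"{spectrum.meta.sample_id!r}"
        )
    values = np.interp(target, spectrum.wavenumbers, spectrum.absorbance)
    return Spectrum(target, values, spectrum.meta)


# ---------------------------------------------------------------------------
# readers / writers


def _default_meta(sample_id: str) -> SpectrumMeta:
    return SpectrumMeta(
        sample_id=sample_id,
        patient_id=sample_id,
        replicate_index=1,
        batch_id="batch0",
    )


def _read_metadata(path) -> dict:
    df = pd.read_csv(path, dtype={"sample_id": str, "patient_id": str, "batch_id": str})
    required = {"sample_id", "patient_id", "replicate_index", "batch_id", "is_qc", "label"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata file missing columns: {sorted(missing)}")
    out = {}
    for row in df.itertuples(index=False):
        is_qc = row.is_qc
        if isinstance(is_qc, str):
            is_qc = is_qc.strip().lower() in ("true", "1", "yes")
        out[row.sample_id] = SpectrumMeta(
            sample_id=row.sample_id,
            patient_id=row.patient_id,
            replicate_index=int(row.replicate_index),
            batch_id=row.batch_id,
            is_qc=bool(is_qc),
            label=row.label,
        )
    return out


def _orient_ascending(grid, values):
    grid = np.asarray(grid, float)
    values = np.asarray(values, float)
    if len(grid) > 1 and grid[0] > grid[-1]:
        return grid[::-1].copy(), values[::-1].copy()
    return grid, values


def _build_spectrum(sample_id, grid, values, meta_by_id):
    if not np.all(np.isfinite(np.asarray(values, float))):
        raise IntegrityError(f"non-finite absorbance in spectrum {sample_id!r}")
    grid, values = _orient_ascending(grid, values)
    meta = meta_by_id.get(sample_id, _default_meta(sample_id)) if meta_by_id is not None \
        else _default_meta(sample_id)
    return Spectrum(grid, values, meta)


def _read_csv_wide(path, meta_by_id):
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2 and not (df.shape[1] >= 1 and df.shape[0] == 0):
        raise FormatError(f"{path}: wide CSV needs sample_id plus wavenumber columns")
    if df.columns[0] != "sample_id":
        raise FormatError(f"{path}: first column must be 'sample_id'")
    try:
        grid = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric wavenumber header: {exc}") from exc
    spectra = []
    for i, row in enumerate(df.itertuples(index=False)):
        values = np.asarray(row[1:], dtype=float)
        if len(values) != len(grid):
            raise FormatError(f"{path}: ragged row {i} ({row[0]!r})")
        spectra.append(_build_spectrum(str(row[0]), grid, values, meta_by_id))
    return spectra


def _read_csv_long(path, meta_by_id):
    df = pd.read_csv(path, dtype={"sample_id": str})
    required = {"sample_id", "wavenumber", "absorbance"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: long CSV needs columns {sorted(required)}")
    spectra = []
    for sid, grp in df.groupby("sample_id", sort=False):
        spectra.append(
            _build_spectrum(
                sid, grp["wavenumber"].to_numpy(), grp["absorbance"].to_numpy(), meta_by_id
            )
        )
    return spectra


def _read_jcampdx_file(path, meta_by_id):
    title = os.path.splitext(os.path.basename(path))[0]
    firstx = lastx = npoints = None
    yfactor = 1.0
    xs, ys = [], []
    in_data = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper()
                value = value.strip()
                if key == "TITLE" and value:
                    title = value
                elif key == "FIRSTX":
                    firstx = float(value)
                elif key == "LASTX":
                    lastx = float(value)
                elif key == "NPOINTS":
                    npoints = int(float(value))
                elif key == "YFACTOR":
                    yfactor = float(value)
                elif key == "XYDATA":
                    in_data = True
                elif key == "END":
                    in_data = False
                continue
            if in_data:
                parts = line.split()
                try:
                    xs.append(float(parts[0]))
                    ys.extend(float(p) * yfactor for p in parts[1:])
                except ValueError as exc:
                    raise FormatError(f"{path}: bad XYDATA line {line!r}") from exc
    if not ys:
        raise FormatError(f"{path}: no XYDATA block found")
    if npoints is not None and npoints != len(ys):
        raise FormatError(
            f"{path}: NPOINTS={npoints} but {len(ys)} y values parsed"
        )
    if firstx is None or lastx is None:
        raise FormatError(f"{path}: FIRSTX/LASTX missing")
    grid = np.linspace(firstx, lastx, len(ys))
    return _build_spectrum(title, grid, np.asarray(ys), meta_by_id)


def read_spectra(path, format: str = "csv_wide", metadata=None) -> SpectraSet:
    """Read a :class:`SpectraSet` from disk.

    Parameters
    ----------
    path:
        File path (for ``jcampdx``: a single file or a directory of
        ``.jdx``/``.dx`` files).
    format:
        One of ``csv_wide``, ``csv_long``, ``jcampdx``.
    metadata:
        Optional path to the sidecar metadata CSV, joined by sample_id.
        Samples absent from the sidecar get placeholder metadata.
    """
    meta_by_id = _read_metadata(metadata) if metadata is not None else None
    if format == "csv_wide":
        spectra = _read_csv_wide(path, meta_by_id)
    elif format == "csv_long":
        spectra = _read_csv_long(path, meta_by_id)
    elif format == "jcampdx":
        if os.path.isdir(path):
            files = sorted(
                os.path.join(path, f)
                for f in os.listdir(path)
                if f.lower().endswith((".jdx", ".dx", ".jcamp"))
            )
            if not files:
                raise FormatError(f"{path}: no JCAMP-DX files found")
            spectra = [_read_jcampdx_file(f, meta_by_id) for f in files]
        else:
            spectra = [_read_jcampdx_file(path, meta_by_id)]
    else:
        raise FormatError(f"unsupported format {format!r}")
    out = SpectraSet(spectra)
    out.log(f"read {len(spectra)} spectra from {path} ({format})")
    return out


def write_spectra(spectra_set: SpectraSet, path, format: str = "csv_wide",
                  metadata=None) -> None:
    """Write a :class:`SpectraSet`; inverse of :func:`read_spectra`.

    If ``metadata`` is given the sidecar CSV is written alongside.
    """
    if format == "csv_wide":
        grid = spectra_set.wavenumbers
        df = pd.DataFrame(
            spectra_set.to_matrix() if len(spectra_set) else np.empty((0, len(grid))),
            columns=[repr(float(w)) for w in grid],
        )
        df.insert(0, "sample_id", spectra_set.sample_ids)
        df.to_csv(path, index=False)
    elif format == "csv_long":
        frames = []
        for s in spectra_set:
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": s.meta.sample_id,
                        "wavenumber": s.wavenumbers,
                        "absorbance": s.absorbance,
                    }
                )
            )
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        else:
            pd.DataFrame(columns=["sample_id", "wavenumber", "absorbance"]).to_csv(
                path, index=False
            )
    elif format == "jcampdx":
        os.makedirs(path, exist_ok=True)
        for s in spectra_set:
            fname = os.path.join(path, f"{s.meta.sample_id}.jdx")
            with open(fname, "w") as fh:
                fh.write(f"##TITLE={s.meta.sample_id}\n")
                fh.write("##JCAMP-DX=4.24\n")
                fh.write("##DATA TYPE=INFRARED SPECTRUM\n")
                fh.write("##XUNITS=1/CM\n##YUNITS=ABSORBANCE\n")
                fh.write(f"##FIRSTX={float(s.wavenumbers[0])!r}\n")
                fh.write(f"##LASTX={float(s.wavenumbers[-1])!r}\n")
                fh.write("##YFACTOR=1.0\n")
                fh.write(f"##NPOINTS={len(s.wavenumbers)}\n")
                fh.write("##XYDATA=(X++(Y..Y))\n")
                for x, y in zip(s.wavenumbers, s.absorbance):
                    fh.write(f"{float(x)!r} {float(y)!r}\n")
                fh.write("##END=\n")
    else:
        raise FormatError(f"unsupported format {format!r}")
    if metadata is not None:
        spectra_set.meta_frame().to_csv(metadata, index=False)
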