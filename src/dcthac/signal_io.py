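"""Readers and writers for labeled single-lead ECG records.

Supported containers:

* delimited text (CSV): one signal per row, or one file per signal inside a
  directory, with labels from a sidecar table, an explicit mapping, or a
  ``<LABEL>_*`` file-naming rule;
* the public "ECGData" MAT-file dialect (a numeric records x samples matrix
  named ``Data`` plus a parallel ``Labels`` cell array), read for full-scale
  reproduction runs;
* a feature-table CSV (``record_id,label,c1..cD``) for persisting extracted
  DCT coefficient vectors at full double precision.

Reading never reorders records, and every write/read pair is an identity on
ids, labels and values.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import (
    DataError,
    FormatError,
    InputError,
    LabelingError,
    ParseError,
)

#: The three-class label alphabet.
LABELS = ("ARR", "CHF", "NSR")

#: Accepted aliases, normalized case-insensitively. "NS" (normal sinus) is a
#: common shorthand for normal sinus rhythm.
_LABEL_ALIASES = {"NS": "NSR"}

DEFAULT_SAMPLING_RATE_HZ = 128.0


def normalize_label(token: object) -> str:
    """Map a raw label token onto the canonical {ARR, CHF, NSR} alphabet.

    Matching is case-insensitive and accepts "NS" as an alias for "NSR".
    """
    lab = str(token).strip().upper()
    lab = _LABEL_ALIASES.get(lab, lab)
    if lab not in LABELS:
        raise LabelingError(
            f"unknown class label {token!r}; expected one of {LABELS} (or 'NS')"
        )
    return lab


@dataclass(frozen=True)
class ECGRecord:
    """One labeled single-lead ECG signal.

    Parameters
    ----------
    record_id : str
        Stable identifier (filename stem, row index, or simulator id).
    samples : numpy.ndarray
        1-D float array of amplitudes in arbitrary units; must be finite
        and non-empty.
    label : str
        One of ``ARR``, ``CHF``, ``NSR`` (aliases normalized).
    sampling_rate_hz : float, default 128.0
        Sampling frequency; the reference recordings are resampled to 128 Hz.
    """

    record_id: str
    samples: np.ndarray
    label: str
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise DataError(f"record {self.record_id!r} contains non-finite samples")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "label", normalize_label(self.label))

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class SignalDataset:
    """An ordered collection of :class:`ECGRecord` sharing one sampling rate."""

    records: list[ECGRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        rates = {r.sampling_rate_hz for r in self.records}
        if len(rates) > 1:
            raise DataError(f"records mix sampling rates: {sorted(rates)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sampling_rate_hz(self) -> float:
        if not self.records:
            return DEFAULT_SAMPLING_RATE_HZ
        return self.records[0].sampling_rate_hz

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    @property
    def class_counts(self) -> dict[str, int]:
        counts = Counter(r.label for r in self.records)
        return {lab: counts.get(lab, 0) for lab in LABELS}

    def subset(self, labels: Iterable[str]) -> "SignalDataset":
        """Records whose label is in `labels`, input order preserved."""
        keep = {normalize_label(l) for l in labels}
        return SignalDataset([r for r in self.records if r.label in keep])


# ---------------------------------------------------------------------------
# delimited text signals
# ---------------------------------------------------------------------------

def _parse_signal_row(row: Sequence[str], where: str, row_no: int) -> np.ndarray:
    values = []
    for col_no, token in enumerate(row, start=1):
        token = token.strip()
        if token == "" and col_no == len(row):
            continue  # trailing comma
        try:
            values.append(float(token))
        except ValueError:
            raise ParseError(
                f"{where}: non-numeric token {token!r} at row {row_no}, field {col_no}"
            ) from None
    if not values:
        raise ParseError(f"{where}: row {row_no} contains no values")
    return np.asarray(values, dtype=np.float64)


def _read_rows(path: Path) -> list[np.ndarray]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        rows = []
        for row_no, row in enumerate(reader, start=1):
            if not row or all(tok.strip() == "" for tok in row):
                continue
            rows.append(_parse_signal_row(row, str(path), row_no))
    return rows


def _label_from_filename(stem: str) -> str | None:
    """Per-file naming rule: leading token before '_' / '-' is the label."""
    for sep in ("_", "-", "."):
        head = stem.split(sep, 1)[0]
        try:
            return normalize_label(head)
        except LabelingError:
            continue
    try:
        return normalize_label(stem)
    except LabelingError:
        return None


def _load_sidecar(path: Path) -> dict[str, str]:
    if not path.exists():
        raise InputError(f"label sidecar not found: {path}")
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or all(t.strip() == "" for t in row):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}: sidecar rows need record_id,label")
            rid, lab = row[0].strip(), row[1].strip()
            if rid.lower() == "record_id":
                continue
            mapping[rid] = lab
    return mapping


def read_delimited_signals(
    path: str | Path,
    labels: Mapping[str, str] | Sequence[str] | str | Path | None = None,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
) -> SignalDataset:
    """Read ECG signals from delimited text.

    Parameters
    ----------
    path : path
        Either a single CSV file (one signal per row) or a directory of
        ``.csv``/``.txt`` files read in lexical order.
    labels : mapping, sequence, path or None
        Label source. A mapping is keyed by ``record_id``; a sequence is
        aligned with record order; a path names a two-column sidecar CSV
        (``record_id,label``). ``None`` falls back to the file-naming rule
        ``<LABEL>_rest.csv`` (directory input only).

    Returns
    -------
    SignalDataset
        Records in input order; ``record_id`` is the filename stem (directory
        input) or ``row<i>`` (single-file input, 0-based).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"signal path not found: {path}")

    sidecar_path: Path | None = None
    if isinstance(labels, (str, Path)):
        sidecar_path = Path(labels).resolve()
        labels = _load_sidecar(Path(labels))

    raw: list[tuple[str, np.ndarray, str | None]] = []  # (id, samples, name-rule label)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".csv", ".txt"}
        )
        # metadata files are never signals
        files = [
            p
            for p in files
            if p.stem.lower() not in {"manifest", "labels"}
            and p.resolve() != sidecar_path
        ]
        if not files:
            raise InputError(f"no .csv/.txt signal files in directory {path}")
        for f in files:
            rows = _read_rows(f)
            name_lab = _label_from_filename(f.stem)
            if len(rows) == 1:
                raw.append((f.stem, rows[0], name_lab))
            else:
                for i, samples in enumerate(rows):
                    raw.append((f"{f.stem}:{i}", samples, name_lab))
    else:
        for i, samples in enumerate(_read_rows(path)):
            raw.append((f"row{i}", samples, None))
        if not raw:
            raise ParseError(f"{path}: no signal rows found")

    if isinstance(labels, Sequence) and not isinstance(labels, (str, bytes)):
        if len(labels) != len(raw):
            raise LabelingError(
                f"{len(labels)} labels given for {len(raw)} records"
            )
        resolved = [normalize_label(l) for l in labels]
    else:
        resolved = []
        for rid, _, name_lab in raw:
            if isinstance(labels, Mapping):
                tok = labels.get(rid, labels.get(rid.split(":", 1)[0]))
                if tok is None:
                    raise LabelingError(f"no label for record {rid!r} in sidecar")
                resolved.append(normalize_label(tok))
            elif name_lab is not None:
                resolved.append(name_lab)
            else:
                raise LabelingError(
                    f"record {rid!r} has no label source (no sidecar, "
                    "filename does not start with a class label)"
                )

    records = [
        ECGRecord(rid, samples, lab, sampling_rate_hz)
        for (rid, samples, _), lab in zip(raw, resolved)
    ]
    return SignalDataset(records)


# ---------------------------------------------------------------------------
# MAT container (public "ECGData" dialect)
# ---------------------------------------------------------------------------

def _cell_to_str(entry: object) -> str:
    x = entry
    while isinstance(x, np.ndarray):
        if x.size != 1 and x.dtype.kind in ("U", "S"):
            x = "".join(str(c) for c in x.ravel())
            break
        x = x.ravel()[0] if x.size >= 1 else ""
    if isinstance(x, bytes):
        x = x.decode()
    return str(x)


def _load_mat_scipy(path: Path) -> tuple[np.ndarray, list[str]]:
    from scipy.io import loadmat

    mat = loadmat(str(path))
    keys = {k.lower(): k for k in mat if not k.startswith("__")}
    data = labels = None
    if "ecgdata" in keys:  # struct ECGData with fields Data, Labels
        struct = mat[keys["ecgdata"]]
        names = struct.dtype.names or ()
        fmap = {n.lower(): n for n in names}
        if "data" not in fmap or "labels" not in fmap:
            raise FormatError(
                f"{path}: ECGData struct lacks Data/Labels fields (has {names})"
            )
        cell = struct[0, 0]
        data = cell[fmap["data"]]
        labels = cell[fmap["labels"]]
    elif "data" in keys and "labels" in keys:
        data, labels = mat[keys["data"]], mat[keys["labels"]]
    else:
        raise FormatError(
            f"{path}: expected variables Data/Labels or an ECGData struct; "
            f"found {sorted(keys.values())}"
        )
    data = np.asarray(data, dtype=np.float64)
    label_list = [_cell_to_str(e) for e in np.asarray(labels, dtype=object).ravel()]
    return data, label_list


def _load_mat_hdf5(path: Path) -> tuple[np.ndarray, list[str]]:
    """MAT v7.3 (HDF5) route; MATLAB stores arrays column-major, so the
    records x samples matrix appears transposed."""
    import h5py

    with h5py.File(path, "r") as fh:
        group = fh["ECGData"] if "ECGData" in fh else fh
        lower = {k.lower(): k for k in group.keys()}
        if "data" not in lower or "labels" not in lower:
            raise FormatError(
                f"{path}: expected Data and Labels datasets; found {list(group)}"
            )
        data = np.asarray(group[lower["data"]], dtype=np.float64).T
        labels = []
        raw = group[lower["labels"]]
        for entry in np.asarray(raw).ravel():
            if isinstance(entry, h5py.Reference):
                chars = np.asarray(fh[entry]).ravel()
                labels.append("".join(chr(int(c)) for c in chars))
            else:
                labels.append(_cell_to_str(entry))
    return data, labels


def read_mat_dataset(
    path: str | Path, sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
) -> SignalDataset:
    """Read the "ECGData" MAT container: a records x samples ``Data`` matrix
    and a parallel ``Labels`` list over {ARR, CHF, NSR}.

    Row *i* of the matrix becomes record *i* with the *i*-th label and
    ``record_id`` ``rec<i>``; the sampling rate defaults to 128 Hz.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"MAT file not found: {path}")
    try:
        data, labels = _load_mat_scipy(path)
    except NotImplementedError:  # MAT v7.3 is HDF5-based
        data, labels = _load_mat_hdf5(path)

    data = np.atleast_2d(data)
    if data.ndim != 2:
        raise FormatError(f"{path}: Data is not a 2-D numeric matrix")
    if data.shape[0] != len(labels):
        raise FormatError(
            f"{path}: {data.shape[0]} signal rows but {len(labels)} labels"
        )
    records = [
        ECGRecord(f"rec{i}", row, lab, sampling_rate_hz)
        for i, (row, lab) in enumerate(zip(data, labels))
    ]
    return SignalDataset(records)


# ---------------------------------------------------------------------------
# feature-table CSV
# ---------------------------------------------------------------------------

def write_feature_table(matrix, path: str | Path) -> None:
    """Write a feature matrix as ``record_id,label,c1..cD`` CSV.

    Values are serialized with 17 significant digits so write/read is a
    bit-exact round trip for doubles.
    """
    path = Path(path)
    width = matrix.width
    header = ["record_id", "label"] + [f"c{j + 1}" for j in range(width)]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rid, lab, row in zip(matrix.record_ids, matrix.labels, matrix.values):
            writer.writerow([rid, lab] + [format(v, ".17g") for v in row])


def read_feature_table(path: str | Path):
    """Read a feature-table CSV written by :func:`write_feature_table`."""
    from .dct_features import FeatureMatrix

    path = Path(path)
    if not path.exists():
        raise InputError(f"feature table not found: {path}")
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header") from None
        if header[:2] != ["record_id", "label"]:
            raise FormatError(
                f"{path}: header must start with record_id,label; got {header[:2]}"
            )
        expected = [f"c{j + 1}" for j in range(len(header) - 2)]
        if header[2:] != expected:
            raise FormatError(
                f"{path}: coefficient columns must be c1..c{len(header) - 2} in order"
            )
        width = len(header) - 2
        ids: list[str] = []
        labels: list[str] = []
        rows: list[list[float]] = []
        for row_no, row in enumerate(reader, start=2):
            if not row or all(t.strip() == "" for t in row):
                continue
            if len(row) != len(header):
                raise FormatError(
                    f"{path}: row {row_no} has {len(row) - 2} values, "
                    f"header declares {width}"
                )
            ids.append(row[0])
            labels.append(normalize_label(row[1]))
            try:
                rows.append([float(t) for t in row[2:]])
            except ValueError:
                raise ParseError(f"{path}: non-numeric value at row {row_no}") from None
    values = np.asarray(rows, dtype=np.float64).reshape(len(rows), width)
    return FeatureMatrix(values=values, labels=labels, record_ids=ids)
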