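"""Reading and writing cytometry data: FCS files, delimited tables, and the
standard preprocessing steps (count de-randomization, ArcSinh transform).

The FCS support is deliberately narrow but standard-conformant: list-mode
FCS 3.0/3.1 with float, double or integer storage is read; files are written
as FCS 3.1, single dataset, ``$DATATYPE F`` (32-bit little-endian float),
which is what modern acquisition and analysis software emits.  Channel
matching across files is by the short parameter name (``$PnN``),
case-sensitive; stain names (``$PnS``) are carried as display aliases only.

Pre-gating (beads, debris, doublets, dead cells) is assumed to have happened
upstream; no gating is performed here.
"""

from __future__ import annotations

import io
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import CytometryDataset, RawSample, ValidationError

#: Recommended ArcSinh cofactors by acquisition platform.
RECOMMENDED_COFACTORS = {"cytof": 5.0, "flow": 150.0, "spectral": 6000.0}

_HEADER_LEN = 58


class FCSFormatError(ValueError):
    """Raised for files that violate the FCS layout this reader supports."""


# ---------------------------------------------------------------------------
# FCS reading
# ---------------------------------------------------------------------------


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    """Parse a TEXT segment into a keyword dict.

    The first byte is the delimiter; a doubled delimiter inside a value is
    an escaped literal delimiter per the standard.
    """
    if not raw:
        raise FCSFormatError("empty TEXT segment")
    text = raw.decode("latin-1")
    delim = text[0]
    # Split then re-merge empty tokens produced by escaped (doubled) delims.
    parts = text[1:].split(delim)
    tokens: list[str] = []
    i = 0
    while i < len(parts):
        tok = parts[i]
        while i + 1 < len(parts) and parts[i + 1] == "" and i + 2 < len(parts):
            tok = tok + delim + parts[i + 2]
            i += 2
        tokens.append(tok)
        i += 1
    if tokens and tokens[-1] == "":
        tokens.pop()
    if len(tokens) % 2:
        raise FCSFormatError("TEXT segment has an odd number of tokens")
    return {tokens[j].strip().upper(): tokens[j + 1] for j in range(0, len(tokens), 2)}


def read_fcs(path: str | Path) -> RawSample:
    """Read a list-mode FCS 3.0/3.1 file into a :class:`RawSample`.

    Channel names are the ``$PnN`` short names; ``$PnS`` stain names, where
    present, are exposed as ``marker_names``.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < _HEADER_LEN:
        raise FCSFormatError(f"{path}: too short to be an FCS file")
    version = data[:6].decode("ascii", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FCSFormatError(f"{path}: unsupported FCS version {version!r}")

    def _offset(lo: int, hi: int) -> int:
        field = data[lo:hi].decode("ascii", errors="replace").strip()
        return int(field) if field else 0

    text_begin, text_end = _offset(10, 18), _offset(18, 26)
    data_begin, data_end = _offset(26, 34), _offset(34, 42)
    kw = _parse_text_segment(data[text_begin : text_end + 1])

    if kw.get("$MODE", "L") != "L":
        raise FCSFormatError("only list-mode ($MODE L) files are supported")
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    dtype_code = kw.get("$DATATYPE", "F").upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    # TEXT-segment offsets override the header when present (large files).
    if int(kw.get("$BEGINDATA", 0) or 0):
        data_begin = int(kw["$BEGINDATA"])
        data_end = int(kw["$ENDDATA"])

    bits = {int(kw.get(f"$P{i}B", 32)) for i in range(1, n_par + 1)}
    if len(bits) != 1:
        raise FCSFormatError("mixed per-parameter bit widths are not supported")
    nbits = bits.pop()
    if dtype_code == "F":
        np_dtype = np.dtype(f"{endian}f4")
        if nbits != 32:
            raise FCSFormatError("$DATATYPE F requires $PnB 32")
    elif dtype_code == "D":
        np_dtype = np.dtype(f"{endian}f8")
        if nbits != 64:
            raise FCSFormatError("$DATATYPE D requires $PnB 64")
    elif dtype_code == "I":
        if nbits not in (8, 16, 32):
            raise FCSFormatError(f"unsupported integer width {nbits}")
        np_dtype = np.dtype(f"{endian}u{nbits // 8}")
    else:
        raise FCSFormatError(f"unsupported $DATATYPE {dtype_code!r}")

    expected = n_tot * n_par * np_dtype.itemsize
    raw = data[data_begin : data_begin + expected]
    if len(raw) < expected:
        raise FCSFormatError(
            f"{path}: DATA segment truncated ({len(raw)} < {expected} bytes)"
        )
    events = np.frombuffer(raw, dtype=np_dtype).reshape(n_tot, n_par).astype(float)

    channel_names = []
    stain_names = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}N", f"P{i}")
        channel_names.append(name)
        stain_names.append(kw.get(f"$P{i}S", name))
    return RawSample(
        events=events,
        channel_names=channel_names,
        marker_names=stain_names,
        source_path=str(path),
    )


# ---------------------------------------------------------------------------
# FCS writing
# ---------------------------------------------------------------------------


def write_fcs(
    sample: RawSample | CytometryDataset | np.ndarray,
    path: str | Path,
    channel_names: list[str] | None = None,
    stain_names: list[str] | None = None,
) -> Path:
    """Write events as a single-dataset FCS 3.1 file (float, list mode).

    Missing-value sentinels (NaN) are refused: imputed values must be
    dropped or filled explicitly before export.
    """
    if isinstance(sample, CytometryDataset):
        events = sample.expression
        channel_names = list(sample.marker_names)
    elif isinstance(sample, RawSample):
        events = sample.events
        channel_names = list(sample.channel_names)
        stain_names = stain_names or sample.marker_names
    else:
        events = np.asarray(sample, dtype=float)
        if channel_names is None:
            raise ValidationError("channel_names required for a bare matrix")
    events = np.asarray(events, dtype=float)
    if events.ndim != 2 or events.shape[1] != len(channel_names):
        raise ValidationError("events shape inconsistent with channel names")
    if events.size and not np.all(np.isfinite(events)):
        raise ValidationError(
            "non-finite values cannot be written to FCS; "
            "drop or fill missing values first"
        )
    stain_names = stain_names or channel_names
    n_tot, n_par = events.shape
    payload = events.astype("<f4").tobytes(order="C")

    def build_text(begin_data: int, end_data: int) -> bytes:
        kv: list[tuple[str, str]] = [
            ("$BEGINANALYSIS", "0"),
            ("$ENDANALYSIS", "0"),
            ("$BEGINSTEXT", "0"),
            ("$ENDSTEXT", "0"),
            ("$BEGINDATA", f"{begin_data:010d}"),
            ("$ENDDATA", f"{end_data:010d}"),
            ("$BYTEORD", "1,2,3,4"),
            ("$DATATYPE", "F"),
            ("$MODE", "L"),
            ("$NEXTDATA", "0"),
            ("$PAR", str(n_par)),
            ("$TOT", str(n_tot)),
        ]
        for i, (cn, sn) in enumerate(zip(channel_names, stain_names), start=1):
            hi = float(np.max(events[:, i - 1])) if n_tot else 0.0
            kv.append((f"$P{i}B", "32"))
            kv.append((f"$P{i}E", "0,0"))
            kv.append((f"$P{i}N", cn))
            kv.append((f"$P{i}R", str(int(max(hi, 1.0)) + 1)))
            if sn and sn != cn:
                kv.append((f"$P{i}S", sn))
        body = "/" + "".join(f"{k}/{v}/" for k, v in kv)
        return body.encode("latin-1")

    # Offsets appear inside TEXT; they are fixed-width so one sizing pass
    # with placeholders suffices.
    text_begin = _HEADER_LEN
    text = build_text(0, 0)
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(payload) - 1 if payload else data_begin
    text = build_text(data_begin, data_end)
    assert text_begin + len(text) - 1 == text_end

    def hfield(value: int) -> bytes:
        s = str(value) if value <= 99_999_999 else "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + b"".join(
        hfield(v)
        for v in (
            text_begin,
            text_end,
            data_begin if data_begin <= 99_999_999 else 0,
            data_end if data_end <= 99_999_999 else 0,
            0,
            0,
        )
    )
    assert len(header) == _HEADER_LEN
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(payload)
    return path


# ---------------------------------------------------------------------------
# Preprocessing transforms
# ---------------------------------------------------------------------------


def derandomize(counts: np.ndarray) -> np.ndarray:
    """Undo CyTOF count randomization by taking the elementwise ceiling.

    Acquisition software randomizes integer ion counts by adding uniform
    noise on (-1, 0); the ceiling maps each randomized value back to its
    original integer exactly.  Integer inputs pass through unchanged.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size and np.min(counts) <= -1:
        raise ValidationError(
            "values <= -1 found; not randomized count data "
            "(randomization noise is uniform on (-1, 0))"
        )
    return np.ceil(counts)


def arcsinh_transform(x: np.ndarray, cofactor: float = 5.0) -> np.ndarray:
    """Variance-stabilizing ArcSinh transform, ``asinh(x / cofactor)``.

    Recommended cofactors: 5 (mass cytometry), 150 (conventional flow),
    6000 (spectral flow).
    """
    if cofactor <= 0:
        raise ValidationError("cofactor must be positive")
    return np.arcsinh(np.asarray(x, dtype=float) / cofactor)


def inverse_arcsinh(y: np.ndarray, cofactor: float = 5.0) -> np.ndarray:
    """Invert :func:`arcsinh_transform`: ``sinh(y) * cofactor``."""
    if cofactor <= 0:
        raise ValidationError("cofactor must be positive")
    return np.sinh(np.asarray(y, dtype=float)) * cofactor


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


def assemble_dataset(
    samples: dict[str, RawSample],
    metadata: pd.DataFrame,
    cofactor: float = 5.0,
    derandomize_flag: bool = False,
) -> CytometryDataset:
    """Combine per-sample event matrices into one ArcSinh-scale dataset.

    Channels are restricted to the intersection across samples and
    canonicalized to sorted order, so input channel order is irrelevant.
    ``metadata`` maps ``sample_id`` to ``batch_id`` and optional
    ``condition``.  De-randomization, when requested, is applied before the
    ArcSinh transform (integer counts are transformed).
    """
    if not samples:
        raise ValidationError("no samples to assemble")
    metadata = metadata.set_index("sample_id") if "sample_id" in metadata else metadata
    missing = [sid for sid in samples if sid not in metadata.index]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing}")

    shared = set(next(iter(samples.values())).channel_names)
    for s in samples.values():
        shared &= set(s.channel_names)
    if not shared:
        raise ValidationError("no overlapping channels across samples")
    channels = sorted(shared)

    blocks, meta_rows = [], []
    for sid, s in samples.items():
        cols = [s.channel_names.index(c) for c in channels]
        x = s.events[:, cols]
        if derandomize_flag:
            x = derandomize(x)
        blocks.append(arcsinh_transform(x, cofactor))
        cond = metadata.loc[sid].get("condition", None)
        if pd.isna(cond):
            cond = None
        meta_rows.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "batch_id": metadata.loc[sid, "batch_id"],
                    "condition": cond,
                    "original_index": np.arange(s.n_events),
                }
            )
        )
    return CytometryDataset(
        expression=np.vstack(blocks),
        marker_names=channels,
        cell_meta=pd.concat(meta_rows, ignore_index=True),
        transform_record={"cofactor": cofactor, "derandomized": derandomize_flag},
    )


# ---------------------------------------------------------------------------
# Delimited-table ingestion (CITE-seq counts and friends)
# ---------------------------------------------------------------------------


def read_table(
    path: str | Path | io.IOBase,
    cofactor: float | None = None,
    sep: str = ",",
) -> CytometryDataset:
    """Read a delimited expression table with a marker header row.

    Metadata columns ``sample_id``/``batch_id``/``condition``/
    ``original_index`` are recognized by name; every other column is a
    marker.  If ``cofactor`` is given the marker values are treated as raw
    intensities/counts and ArcSinh-transformed; otherwise they are taken to
    be on the ArcSinh scale already.
    """
    df = pd.read_csv(path, sep=sep)
    record = {}
    if cofactor is not None:
        from .dataset import META_COLUMNS

        markers = [c for c in df.columns if c not in META_COLUMNS]
        df[markers] = arcsinh_transform(df[markers].to_numpy(), cofactor)
        record = {"cofactor": cofactor, "derandomized": False}
    return CytometryDataset.from_dataframe(df, transform_record=record)


def write_table(dataset: CytometryDataset, path: str | Path, sep: str = ",") -> Path:
    dataset.to_dataframe().to_csv(path, sep=sep, index=False)
    return Path(path)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet CSV (sample_id, batch_id[, condition, filename])."""
    sheet = pd.read_csv(path, dtype={"sample_id": str, "batch_id": str})
    for col in ("sample_id", "batch_id"):
        if col not in sheet.columns:
            raise ValidationError(f"sample sheet missing column {col!r}")
    if "condition" not in sheet.columns:
        sheet["condition"] = None
    return sheet
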