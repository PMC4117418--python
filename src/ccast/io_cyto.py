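"""Reading, transforming and column-selecting cytometry event data.

Cytometry experiments record, for every cell (event), the intensity of a
panel of fluorescent or metal-isotope reporters ("markers").  The data live
either in binary Flow Cytometry Standard (FCS) files or in delimited text
with one row per cell and one column per marker.  This module provides the
:class:`ExpressionTable` container used by the rest of the package, a
read-only FCS 2.0/3.0/3.1 list-mode parser, delimited-text round-tripping,
the variance-stabilizing arcsinh transform, and marker selection.

Compensation (spillover correction) is assumed to have been applied
upstream; negative and zero intensities are retained untouched, since the
arcsinh transform handles both.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTable",
    "FCSParseError",
    "read_events",
    "write_events",
    "arcsinh_transform",
    "select_markers",
    "MASS_COFACTOR",
    "FLUOR_COFACTOR",
]

#: conventional arcsinh cofactor for mass cytometry (CyTOF) data
MASS_COFACTOR = 5.0
#: conventional arcsinh cofactor for fluorescence flow cytometry data
FLUOR_COFACTOR = 150.0


class FCSParseError(ValueError):
    """Raised when an FCS file cannot be parsed; the message names the
    offending segment (HEADER, TEXT or DATA)."""


@dataclass(frozen=True)
class ExpressionTable:
    """A cells x markers table of real-valued intensities.

    Parameters
    ----------
    values
        ``(n_cells, n_markers)`` float array; all entries finite.
    marker_names
        Pairwise-distinct marker names, one per column.
    event_ids
        Unique integer identifier per row (cell/event).
    transformed
        Whether :func:`arcsinh_transform` has been applied.
    """

    values: np.ndarray
    marker_names: tuple[str, ...]
    event_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    transformed: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D cells x markers array")
        n, r = values.shape
        if n < 1 or r < 1:
            raise ValueError("need at least one cell and one marker")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite intensity values")
        names = tuple(str(m) for m in self.marker_names)
        if len(names) != r:
            raise ValueError(
                f"{len(names)} marker names for {r} columns"
            )
        if len(set(names)) != len(names):
            dupes = sorted({m for m in names if names.count(m) > 1})
            raise ValueError(f"duplicate marker names: {dupes}")
        ids = self.event_ids
        ids = np.arange(n) if ids is None else np.asarray(ids, dtype=int)
        if ids.shape != (n,):
            raise ValueError("event_ids must have one entry per cell")
        if len(np.unique(ids)) != n:
            raise ValueError("event_ids must be unique")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "marker_names", names)
        object.__setattr__(self, "event_ids", ids)

    # -- basic accessors -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def marker_index(self, name: str) -> int:
        try:
            return self.marker_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown marker {name!r}; available: {list(self.marker_names)}"
            ) from None

    def marker(self, name: str) -> np.ndarray:
        """Column of intensities for a single named marker."""
        return self.values[:, self.marker_index(name)]

    def subset_events(self, index: np.ndarray) -> "ExpressionTable":
        """Row-subset (boolean mask or integer positions), order preserved."""
        index = np.asarray(index)
        return replace(
            self, values=self.values[index], event_ids=self.event_ids[index]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, columns=list(self.marker_names), copy=True
        )


# ---------------------------------------------------------------------------
# FCS parsing.  Minimal list-mode reader: HEADER offsets, TEXT keywords,
# uniform-width DATA segment of type F/D/I.  Escaped (doubled) delimiters in
# TEXT values are not supported.
# ---------------------------------------------------------------------------

_FCS_VERSIONS = {"FCS2.0", "FCS3.0", "FCS3.1"}


def _header_offset(raw: bytes, lo: int, hi: int, what: str) -> int:
    text = raw[lo:hi].decode("ascii", "replace").strip()
    if text == "":
        return 0
    try:
        return int(text)
    except ValueError:
        raise FCSParseError(f"HEADER: non-numeric {what} offset {text!r}") from None


def _parse_text_segment(raw: bytes, begin: int, end: int) -> dict[str, str]:
    if begin <= 0 or end <= begin or end >= len(raw):
        raise FCSParseError("TEXT: segment offsets invalid or file truncated")
    delim = chr(raw[begin])
    body = raw[begin + 1 : end + 1].decode("latin-1")
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        raise FCSParseError("TEXT: odd number of key/value tokens")
    kw: dict[str, str] = {}
    for key, val in zip(parts[::2], parts[1::2]):
        kw[key.strip().upper()] = val.strip()
    return kw


def _read_fcs(path: Path) -> tuple[np.ndarray, list[str]]:
    raw = path.read_bytes()
    if len(raw) < 58:
        raise FCSParseError("HEADER: file shorter than the 58-byte FCS header")
    version = raw[:6].decode("ascii", "replace")
    if version not in _FCS_VERSIONS:
        raise FCSParseError(f"HEADER: unsupported version {version!r}")
    text_begin = _header_offset(raw, 10, 18, "TEXT begin")
    text_end = _header_offset(raw, 18, 26, "TEXT end")
    data_begin = _header_offset(raw, 26, 34, "DATA begin")
    data_end = _header_offset(raw, 34, 42, "DATA end")

    kw = _parse_text_segment(raw, text_begin, text_end)

    if data_begin == 0:  # large files store DATA offsets in TEXT (FCS 3.x)
        try:
            data_begin = int(kw["$BEGINDATA"])
            data_end = int(kw["$ENDDATA"])
        except (KeyError, ValueError):
            raise FCSParseError("DATA: no usable offsets in HEADER or TEXT") from None

    mode = kw.get("$MODE", "L")
    if mode != "L":
        raise FCSParseError(f"DATA: only list mode supported, got $MODE={mode}")
    try:
        par = int(kw["$PAR"])
        tot = int(kw["$TOT"])
        datatype = kw["$DATATYPE"]
        byteord = kw["$BYTEORD"]
    except KeyError as exc:
        raise FCSParseError(f"TEXT: missing required keyword {exc}") from None

    order = {"1,2,3,4": "<", "4,3,2,1": ">", "1,2": "<", "2,1": ">"}.get(byteord)
    if order is None:
        raise FCSParseError(f"TEXT: unsupported $BYTEORD {byteord!r}")

    if datatype == "F":
        dtype = np.dtype(order + "f4")
    elif datatype == "D":
        dtype = np.dtype(order + "f8")
    elif datatype == "I":
        bits = {int(kw.get(f"$P{i}B", "0")) for i in range(1, par + 1)}
        if len(bits) != 1 or bits.pop() not in (8, 16, 32, 64):
            raise FCSParseError("DATA: integer data requires a uniform $PnB of 8/16/32/64")
        nbits = int(kw["$P1B"])
        dtype = np.dtype(order + f"u{nbits // 8}")
    else:
        raise FCSParseError(f"DATA: unsupported $DATATYPE {datatype!r}")

    count = par * tot
    nbytes = count * dtype.itemsize
    if data_begin + nbytes - 1 > min(data_end, len(raw) - 1):
        raise FCSParseError(
            f"DATA: segment truncated; need {nbytes} bytes for "
            f"{tot} events x {par} parameters"
        )
    values = (
        np.frombuffer(raw, dtype=dtype, count=count, offset=data_begin)
        .reshape(tot, par)
        .astype(float)
    )

    # log-amplified integer channels: decode x -> 10^(f1*x/range) * f2
    if datatype == "I":
        for i in range(par):
            amp = kw.get(f"$P{i + 1}E", "0,0")
            try:
                f1, f2 = (float(v) for v in amp.split(","))
            except ValueError:
                raise FCSParseError(f"TEXT: malformed $P{i + 1}E={amp!r}") from None
            if f1 != 0.0:
                rng = float(kw.get(f"$P{i + 1}R", "1024"))
                values[:, i] = 10.0 ** (f1 * values[:, i] / rng) * (f2 or 1.0)

    names = []
    for i in range(1, par + 1):
        name = kw.get(f"$P{i}S", "").strip() or kw.get(f"$P{i}N", "").strip()
        names.append(name or f"P{i}")
    return values, names


# ---------------------------------------------------------------------------
# Public reading / writing
# ---------------------------------------------------------------------------


def read_events(path: str | Path, format: str | None = None) -> ExpressionTable:
    """Read raw (untransformed) cytometry events from FCS or delimited text.

    ``format`` is ``"fcs"`` or ``"delimited"``; when omitted it is inferred
    from the file extension and, failing that, from the leading magic bytes.
    Marker names come from FCS ``$PnS``, falling back to ``$PnN``; for
    delimited files the header row supplies them.  Event ids are assigned
    ``0..n-1`` in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        if path.suffix.lower() == ".fcs":
            format = "fcs"
        elif path.suffix.lower() in (".csv", ".tsv", ".txt"):
            format = "delimited"
        else:
            with open(path, "rb") as fh:
                format = "fcs" if fh.read(3) == b"FCS" else "delimited"
    if format == "fcs":
        values, names = _read_fcs(path)
    elif format == "delimited":
        if path.suffix.lower() == ".tsv":
            sep = "\t"
        else:  # sniff the delimiter from the header row
            import csv

            with open(path, newline="") as fh:
                sep = csv.Sniffer().sniff(fh.readline(), delimiters=",\t;").delimiter
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
        names = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown format {format!r}; use 'fcs' or 'delimited'")
    return ExpressionTable(values=values, marker_names=tuple(names))


def write_events(table: ExpressionTable, path: str | Path, sep: str | None = None) -> Path:
    """Write a table as delimited text (header = marker names).

    Values are printed with shortest-round-trip precision, so a
    write-then-read cycle reproduces them exactly.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
    table.to_dataframe().to_csv(path, sep=sep, index=False)
    return path


def arcsinh_transform(table: ExpressionTable, cofactor: float = MASS_COFACTOR) -> ExpressionTable:
    """Apply ``asinh(value / cofactor)`` to every intensity.

    The transform is strictly increasing and odd, behaves like
    ``log(2 v / cofactor)`` for large values and linearly near zero, and is
    the field-standard variance stabilization for cytometry.  Conventional
    cofactors: 5 for mass cytometry, 150 for fluorescence.
    """
    if table.transformed:
        raise ValueError("table is already arcsinh-transformed")
    if not cofactor > 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    return replace(table, values=np.arcsinh(table.values / cofactor), transformed=True)


def select_markers(table: ExpressionTable, names: list[str]) -> ExpressionTable:
    """Column-subset (and reorder) the table to the given markers.

    Row order and event ids are preserved; unknown names raise ``KeyError``
    listing the available markers.
    """
    idx = [table.marker_index(n) for n in names]
    return replace(table, values=table.values[:, idx], marker_names=tuple(names))
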