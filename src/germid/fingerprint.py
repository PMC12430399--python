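"""Accession fingerprint records, canonical QR payloads, and map export.

A :class:`FingerprintRecord` joins an accession's core-marker genotype code
with its coded trait values. The QR payload is a canonical, lossless text
grammar:

    GERMFP1
    id=<accession>
    fp=<code>
    traits=<name>:<value>;<name>:<value>;...

Reserved characters (``=``, ``;``, ``:``, ``%``, newline) inside ids, names
or values are percent-escaped, so encode -> parse -> encode is byte-identical
and payloads are injective over record content. Missing trait values are
rendered as ``NA``.

``export_map`` writes one PNG per accession (decoded back and verified
against its payload) plus a CSV table and an xlsx workbook referencing the
images — the "one code, one image" map.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import qr

PAYLOAD_VERSION = "GERMFP1"
MISSING_TOKEN = "NA"

_ESCAPES = [("%", "%25"), ("=", "%3D"), (";", "%3B"), (":", "%3A"), ("\n", "%0A")]


def _escape(text: str) -> str:
    for raw, enc in _ESCAPES:
        text = text.replace(raw, enc)
    return text


def _unescape(text: str) -> str:
    for raw, enc in reversed(_ESCAPES):
        text = text.replace(enc, raw)
    return text


@dataclass
class FingerprintRecord:
    accession_id: str
    code: str  # "|"-separated genotype tokens over the core loci
    traits: dict[str, str] = field(default_factory=dict)
    payload_version: str = PAYLOAD_VERSION


def build_records(codes: pd.Series, traits: pd.DataFrame) -> list[FingerprintRecord]:
    """One record per sample in ``codes``; trait rows joined by accession id.

    Raises a join error listing every accession missing from the trait table.
    """
    missing = [sid for sid in codes.index if sid not in traits.index]
    if missing:
        raise KeyError(f"accessions absent from trait table: {missing}")
    records = []
    for sid, code in codes.items():
        row = traits.loc[sid]
        vals = {
            str(t): (MISSING_TOKEN if pd.isna(v) else _format_value(v))
            for t, v in row.items()
        }
        records.append(FingerprintRecord(accession_id=str(sid), code=code, traits=vals))
    return records


def _format_value(v) -> str:
    if isinstance(v, float) and v == int(v):
        return str(int(v))
    return str(v)


def qr_payload(record: FingerprintRecord) -> str:
    """Canonical payload text for one record (deterministic, lossless)."""
    traits = ";".join(
        f"{_escape(k)}:{_escape(str(v))}" for k, v in record.traits.items()
    )
    return "\n".join(
        [record.payload_version,
         f"id={_escape(record.accession_id)}",
         f"fp={_escape(record.code)}",
         f"traits={traits}"]
    )


def parse_payload(text: str) -> FingerprintRecord:
    """Inverse of :func:`qr_payload`."""
    lines = text.split("\n")
    if len(lines) != 4 or not lines[0].startswith("GERMFP"):
        raise ValueError("not a recognisable fingerprint payload")
    version = lines[0]
    fields = {}
    for line in lines[1:]:
        key, _, val = line.partition("=")
        fields[key] = val
    traits = {}
    if fields.get("traits"):
        for item in fields["traits"].split(";"):
            k, _, v = item.partition(":")
            traits[_unescape(k)] = _unescape(v)
    return FingerprintRecord(
        accession_id=_unescape(fields["id"]),
        code=_unescape(fields["fp"]),
        traits=traits,
        payload_version=version,
    )


@dataclass
class QRVerification:
    path: Path
    version: int
    n_modules: int
    verified: bool


def render_and_verify_qr(payload: str, out_path, scale: int = 4) -> QRVerification:
    """Write the payload as a PNG and decode it back, asserting byte equality."""
    if not payload:
        raise ValueError("empty payload")
    symbol = qr.encode(payload)
    img = symbol.to_image(scale=scale)
    out_path = Path(out_path)
    img.save(out_path, format="PNG")
    decoded = qr.decode_image(out_path).decode("utf-8")
    if decoded != payload:
        raise qr.QRDecodeError(f"round-trip mismatch for {out_path}")
    return QRVerification(path=out_path, version=symbol.version,
                          n_modules=symbol.n_modules, verified=True)


def export_map(records: list[FingerprintRecord], out_dir, scale: int = 4,
               write_xlsx: bool = True) -> pd.DataFrame:
    """Write the one-code-one-image fingerprint map.

    Produces ``qr/<accession>.png`` per record (each verified by decode),
    ``fingerprint_map.csv`` and optionally ``fingerprint_map.xlsx``.
    Returns the map table.
    """
    if not records:
        raise ValueError("no records to export")
    ids = [r.accession_id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate accession ids")
    out_dir = Path(out_dir)
    img_dir = out_dir / "qr"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in sorted(records, key=lambda r: r.accession_id):
        payload = qr_payload(rec)
        png = img_dir / f"{rec.accession_id}.png"
        render_and_verify_qr(payload, png, scale=scale)
        rows.append(
            {"accession_id": rec.accession_id, "fingerprint_code": rec.code,
             "qr_image": str(png.relative_to(out_dir))}
        )
    table = pd.DataFrame(rows)
    csv_path = out_dir / "fingerprint_map.csv"
    table.to_csv(csv_path, index=False, quoting=csv.QUOTE_MINIMAL)
    if write_xlsx:
        _write_xlsx(table, out_dir / "fingerprint_map.xlsx")
    return table


def _write_xlsx(table: pd.DataFrame, path: Path) -> None:
    from openpyxl import Workbook

    wb = Workbook()
    ws = wb.active
    ws.title = "fingerprints"
    ws.append(["Sample ID", "SNP Fingerprint Code", "QR Code image"])
    for _, row in table.iterrows():
        ws.append([row["accession_id"], row["fingerprint_code"], row["qr_image"]])
    wb.save(path)
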