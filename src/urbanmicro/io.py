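"""Readers/writers for abundance tables.

TSV is the canonical interchange format: first column ``otu_id``, second
column the semicolon-delimited taxonomy lineage, remaining columns per-sample
integer counts.  BIOM 2.x (HDF5) tables — the output format of read
classifiers such as Kraken via kraken-biom — are supported read-only,
decoded directly from the documented HDF5 CSR layout.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np

from .data import AbundanceTable, ValidationError, _pad_lineage

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised for malformed input files; names the offending line or record."""


def read_abundance(path, format: str = "tsv") -> AbundanceTable:
    """Read an abundance table from ``path``.

    Parameters
    ----------
    path
        Input file.
    format
        ``"tsv"`` or ``"biom"`` (BIOM 2.x HDF5).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom":
        return _read_biom(path)
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'biom'")


def _read_tsv(path: Path) -> AbundanceTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}:1: empty header line")
        cols = header.split("\t")
        if len(cols) < 3:
            raise ParseError(f"{path}:1: expected otu_id, lineage and >=1 sample column")
        sample_ids = cols[2:]
        otu_ids: list[str] = []
        lineages: dict[str, tuple[str, ...]] = {}
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(cols)} fields, found {len(parts)}"
                )
            otu_id, lineage_str = parts[0], parts[1]
            values = []
            for s, raw in zip(sample_ids, parts[2:]):
                try:
                    v = int(raw)
                except ValueError as exc:
                    raise ValidationError(
                        f"{path}:{lineno}: non-integer count {raw!r} for sample {s}"
                    ) from exc
                if v < 0:
                    raise ValidationError(
                        f"{path}:{lineno}: negative count {v} for sample {s}"
                    )
                values.append(v)
            otu_ids.append(otu_id)
            lineages[otu_id] = _pad_lineage(lineage_str.split(";"))
            rows.append(values)
    counts = np.asarray(rows, dtype=np.int64) if rows else np.zeros((0, len(sample_ids)), dtype=np.int64)
    return AbundanceTable(otu_ids, lineages, counts, sample_ids)


def write_abundance(table: AbundanceTable, path) -> None:
    """Write a table in the canonical TSV dialect (bit-exact round-trip)."""
    with open(path, "w") as fh:
        fh.write("otu_id\tlineage\t" + "\t".join(table.sample_ids) + "\n")
        for i, otu in enumerate(table.otu_ids):
            lineage = ";".join(table.lineages[otu])
            row = "\t".join(str(int(v)) for v in table.counts[i])
            fh.write(f"{otu}\t{lineage}\t{row}\n")


def _decode(values) -> list[str]:
    return [v.decode() if isinstance(v, bytes) else str(v) for v in values]


def _read_biom(path: Path) -> AbundanceTable:
    """Decode a BIOM 2.x HDF5 table (observations = OTUs, CSR layout)."""
    with h5py.File(path, "r") as h5:
        try:
            otu_ids = _decode(h5["observation/ids"][...])
            sample_ids = _decode(h5["sample/ids"][...])
            data = h5["observation/matrix/data"][...]
            indices = h5["observation/matrix/indices"][...]
            indptr = h5["observation/matrix/indptr"][...]
        except KeyError as exc:
            raise ParseError(f"{path}: missing BIOM 2.x dataset {exc}") from exc
        counts = np.zeros((len(otu_ids), len(sample_ids)), dtype=np.int64)
        int_data = np.asarray(data)
        if not np.all(int_data == np.floor(int_data)):
            bad = int(np.argwhere(int_data != np.floor(int_data))[0][0])
            raise ValidationError(f"{path}: non-integer count at data record {bad}")
        for i in range(len(otu_ids)):
            lo, hi = indptr[i], indptr[i + 1]
            counts[i, indices[lo:hi]] = int_data[lo:hi].astype(np.int64)
        lineages: dict[str, tuple[str, ...]] = {}
        taxonomy = h5.get("observation/metadata/taxonomy")
        if taxonomy is not None:
            tax = taxonomy[...]
            for i, otu in enumerate(otu_ids):
                lineages[otu] = _pad_lineage(_strip_prefixes(_decode(tax[i])))
        else:
            logger.warning("%s: no taxonomy metadata; lineages set to unclassified", path)
            for otu in otu_ids:
                lineages[otu] = _pad_lineage([])
    return AbundanceTable(otu_ids, lineages, counts, sample_ids)


def _strip_prefixes(lineage: list[str]) -> list[str]:
    """Drop greengenes-style rank prefixes ('k__Bacteria' -> 'Bacteria')."""
    out = []
    for part in lineage:
        part = part.strip()
        if len(part) >= 3 and part[1:3] == "__":
            part = part[3:]
        out.append(part)
    return out
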