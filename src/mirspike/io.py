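"""Readers and writers for the neutral text formats the pipeline uses.

Formats (all tab-separated with a header, or FASTA):

* Ct table:       sample_id  replicate_id  assay_id  ct
                  (``ct`` is a decimal or the token ``Undetermined``;
                  ``NA`` and the empty string are accepted on read)
* Assay catalog:  assay_id  platform_id  target_mirna_id  target_sequence
* Spike design:   sample_id  mirna_id  copies_per_reaction
* Panel:          FASTA; pool labels either as a ``pool=A`` token in the
                  description line or via a sidecar TSV (mirna_id, pool).

Vendor instrument exports (SDS/EDS) are out of scope; convert to the
neutral schema first.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AssayCatalog,
    AssayRecord,
    CtTable,
    DuplicateKeyError,
    MiRNAPanel,
    MiRNASpecies,
    SpikeDesign,
    ValidationError,
)

__all__ = [
    "UNDETECTED_TOKENS",
    "read_ct_table",
    "write_ct_table",
    "read_panel",
    "write_panel",
    "read_catalog",
    "write_catalog",
    "read_design",
    "write_design",
]

#: File tokens accepted as the UNDETECTED sentinel. "Undetermined" is
#: canonical on write; the others cover common spreadsheet exports.
UNDETECTED_TOKENS = ("Undetermined", "NA", "")


def read_ct_table(path: str | Path, max_cycles: float = 40.0) -> CtTable:
    """Read a long-form Ct TSV; ``Undetermined``/``NA``/empty -> UNDETECTED.

    Raises on missing columns, duplicate (sample, replicate, assay) keys,
    unparseable Ct tokens, and Ct values outside (0, max_cycles].
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "replicate_id", "assay_id", "ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    raw = df["ct"].str.strip()
    ct = pd.Series(np.nan, index=df.index, dtype=float)
    numeric_mask = ~raw.isin(UNDETECTED_TOKENS)
    try:
        ct[numeric_mask] = raw[numeric_mask].astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: unparseable ct value ({exc})") from None
    out = df[["sample_id", "replicate_id", "assay_id"]].copy()
    out["ct"] = ct
    try:
        return CtTable(out, max_cycles=max_cycles)
    except ValidationError as exc:
        raise type(exc)(f"{path}: {exc}") from None


def write_ct_table(table: CtTable, path: str | Path) -> None:
    df = table.df.copy()
    df["ct"] = df["ct"].map(lambda v: "Undetermined" if np.isnan(v) else repr(float(v)))
    df.to_csv(path, sep="\t", index=False)


def _pool_from_description(description: str) -> str | None:
    for token in description.split():
        if token.startswith("pool="):
            return token[len("pool=") :]
    return None


def read_panel(
    path: str | Path, pool_map: Mapping[str, str] | str | Path | None = None
) -> MiRNAPanel:
    """Read a panel FASTA.

    Pool labels come from ``pool_map`` (an id->pool mapping or the path of a
    sidecar TSV with columns mirna_id, pool) or, failing that, from a
    ``pool=A`` token on the description line.  Sequences are normalized to
    the DNA alphabet (U -> T).
    """
    if pool_map is not None and not isinstance(pool_map, Mapping):
        side = pd.read_csv(pool_map, sep="\t", dtype=str)
        if not {"mirna_id", "pool"} <= set(side.columns):
            raise ValidationError(f"{pool_map}: sidecar needs mirna_id, pool columns")
        pool_map = dict(zip(side["mirna_id"], side["pool"]))
    species = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if pool_map is not None and rec.id in pool_map:
            pool = pool_map[rec.id]
        else:
            pool = _pool_from_description(rec.description)
        if pool is None:
            raise ValidationError(f"{path}: no pool label for {rec.id}")
        species.append(MiRNASpecies(rec.id, str(rec.seq), pool))
    if not species:
        raise ValidationError(f"{path}: no FASTA records")
    return MiRNAPanel(species)


def write_panel(panel: MiRNAPanel, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(sp.sequence), id=sp.mirna_id, description=f"pool={sp.pool}")
        for sp in panel
    ]
    SeqIO.write(records, str(path), "fasta")


def read_catalog(path: str | Path) -> AssayCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["assay_id", "platform_id", "target_mirna_id", "target_sequence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    records = [
        AssayRecord(
            assay_id=row.assay_id,
            platform_id=row.platform_id,
            target_mirna_id=row.target_mirna_id or None,
            target_sequence=row.target_sequence,
        )
        for row in df.itertuples(index=False)
    ]
    return AssayCatalog(records)


def write_catalog(catalog: AssayCatalog, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["assay_id", "platform_id", "target_mirna_id", "target_sequence"])
        for rec in catalog:
            writer.writerow(
                [rec.assay_id, rec.platform_id, rec.target_mirna_id or "", rec.target_sequence]
            )


def read_design(path: str | Path) -> SpikeDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "mirna_id", "copies_per_reaction"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    copies: dict[tuple[str, str], float] = {}
    for row in df.itertuples(index=False):
        key = (row.sample_id, row.mirna_id)
        if key in copies:
            raise DuplicateKeyError(f"{path}: duplicate design entry {key}")
        copies[key] = float(row.copies_per_reaction)
    return SpikeDesign(copies)


def write_design(design: SpikeDesign, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "mirna_id", "copies_per_reaction"])
        for (sample, mirna), c in design.items():
            writer.writerow([sample, mirna, repr(float(c))])
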