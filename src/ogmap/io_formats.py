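"""File formats of the optical-mapping pipeline.

Covers reference FASTA reading with motif-site extraction (the labeled motif
CTTAAG is palindromic, so a forward-strand scan covers both strands), the
Bionano BNX molecule/localization text format (version 1.2/1.3 record
structure: ``#`` header lines, then per molecule a ``0`` metadata line, a
``1`` label-position line and optional quality lines), digital cropping of
BNX label lists, and plain TSV site-map / query-map tables.

All coordinates are 0-based with half-open intervals internally; BNX native
conventions (label line terminated by the molecule end position, fixed
two-decimal formatting) are preserved on write so round-trips are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .aligner import QueryMap, ReferenceMap

__all__ = [
    "BnxMolecule",
    "FormatError",
    "DEFAULT_MOTIF",
    "find_motif_sites",
    "read_fasta_reference",
    "reference_maps_from_fasta",
    "read_bnx",
    "write_bnx",
    "crop_bnx_molecule",
    "bnx_to_query_map",
    "write_site_map",
    "read_site_map",
    "write_query_maps",
    "read_query_maps",
]

DEFAULT_MOTIF = "CTTAAG"


class FormatError(ValueError):
    """Raised on malformed input files."""


# ---------------------------------------------------------------------------
# FASTA and motif maps
# ---------------------------------------------------------------------------

def find_motif_sites(sequence: str, motif: str = DEFAULT_MOTIF) -> ReferenceMap:
    """0-based start positions of every motif occurrence, both strands.

    The default motif CTTAAG equals its own reverse complement, so the
    forward-strand scan already covers both strands; for non-palindromic
    motifs the reverse complement is searched too and reported in forward
    coordinates, deduplicated.  Windows containing N never match.
    """
    motif = motif.upper()
    if not motif or any(c not in "ACGT" for c in motif):
        raise ValueError("motif must be a nonempty string over A/C/G/T")
    seq = sequence.upper()
    if any(c not in "ACGTN" for c in set(seq)):
        raise ValueError("sequence contains characters outside A/C/G/T/N")
    rc = str(Seq(motif).reverse_complement())
    patterns = {motif} | {rc}
    hits: set[int] = set()
    for pat in patterns:
        start = seq.find(pat)
        while start != -1:
            hits.add(start)
            start = seq.find(pat, start + 1)  # overlapping occurrences count
    return ReferenceMap(
        positions_bp=np.array(sorted(hits), dtype=np.float64),
        sequence_length_bp=len(seq),
    )


def read_fasta_reference(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly multi-record) FASTA into (id, sequence) pairs.

    IDs are the first whitespace-delimited header token; sequences are
    upper-cased.  Empty files and records without sequence raise
    :class:`FormatError`.
    """
    path = Path(path)
    text_head = path.read_text()[:1] if path.stat().st_size else ""
    if text_head != ">":
        raise FormatError(f"{path}: not a FASTA file (missing '>' header)")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has no sequence lines")
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def reference_maps_from_fasta(path: str | Path, motif: str = DEFAULT_MOTIF) -> list[ReferenceMap]:
    """Build one motif-site ReferenceMap per FASTA record."""
    maps = []
    for seq_id, seq in read_fasta_reference(path):
        ref = find_motif_sites(seq, motif)
        maps.append(replace(ref, sequence_id=seq_id))
    return maps


# ---------------------------------------------------------------------------
# BNX
# ---------------------------------------------------------------------------

DEFAULT_BNX_HEADER = (
    "# BNX File Version:\t1.2",
    "# Label Channels:\t1",
    "#0h\tLabelChannel\tMoleculeID\tLength",
    "#0f\tint\tint\tfloat",
    "#1h\tLabelChannel\tLabelPositions[N]",
)


@dataclass(frozen=True)
class BnxMolecule:
    """One BNX molecule: metadata line, label positions and quality lines.

    ``label_positions`` are in the file's native units (nanometre-derived
    basepairs for instrument output); conversion to pixels happens only at
    the QueryMap boundary.  ``crop_offset`` records the cumulative window
    start of digital crops so ground-truth placement stays recoverable.
    """

    molecule_id: str
    length: float
    label_positions: np.ndarray
    extra_fields: tuple[str, ...] = ()
    aux_lines: tuple[str, ...] = ()
    crop_offset: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.label_positions, dtype=np.float64)
        object.__setattr__(self, "label_positions", p)
        if self.length <= 0:
            raise ValueError("molecule length must be positive")
        if p.size and (np.any(np.diff(p) < 0)):
            raise ValueError("label positions must be increasing")
        if p.size and (p[0] < 0 or p[-1] > self.length):
            raise ValueError("label positions must lie within the molecule length")


def read_bnx(path: str | Path) -> list[BnxMolecule]:
    """Parse a BNX 1.2/1.3-style file into molecule records.

    The trailing entry of each ``1`` line equals the molecule length (the
    BNX end marker) and is dropped from ``label_positions``; quality lines
    (``QX11`` etc.) are preserved verbatim.
    """
    path = Path(path)
    molecules: list[BnxMolecule] = []
    version_seen = None
    current: dict | None = None

    def flush(lineno: int) -> None:
        nonlocal current
        if current is None:
            return
        if current["positions"] is None:
            raise FormatError(f"{path}:{lineno}: molecule {current['id']} has no label line")
        molecules.append(
            BnxMolecule(
                molecule_id=current["id"],
                length=current["length"],
                label_positions=np.array(current["positions"], dtype=np.float64),
                extra_fields=tuple(current["extra"]),
                aux_lines=tuple(current["aux"]),
            )
        )
        current = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.lower().startswith("# bnx file version:"):
                    version_seen = line.split(":", 1)[1].strip()
                    if version_seen not in ("1.2", "1.3"):
                        raise FormatError(
                            f"{path}:{lineno}: unsupported BNX version {version_seen!r}"
                        )
                continue
            fields = line.split("\t")
            if fields[0] == "0":
                flush(lineno)
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: truncated molecule line")
                current = {
                    "id": fields[1],
                    "length": float(fields[2]),
                    "extra": fields[3:],
                    "positions": None,
                    "aux": [],
                }
            elif fields[0] == "1":
                if current is None:
                    raise FormatError(f"{path}:{lineno}: label line outside a molecule record")
                values = [float(v) for v in fields[1:]]
                if values and abs(values[-1] - current["length"]) < 0.005:
                    values = values[:-1]  # end marker
                if values and values[-1] > current["length"]:
                    raise FormatError(
                        f"{path}:{lineno}: label position exceeds molecule length"
                    )
                current["positions"] = values
            else:
                if current is None:
                    raise FormatError(f"{path}:{lineno}: unexpected line {fields[0]!r}")
                current["aux"].append(line)
    flush(-1)
    return molecules


def _fmt(v: float) -> str:
    return f"{v:.2f}"


def write_bnx(
    molecules: list[BnxMolecule], path: str | Path, header: tuple[str, ...] = DEFAULT_BNX_HEADER
) -> None:
    """Write molecules in the same dialect :func:`read_bnx` parses.

    Positions use fixed two-decimal formatting and the label line is closed
    with the molecule length, so write -> read -> write is bit-identical.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        for mol in molecules:
            zero = ["0", mol.molecule_id, _fmt(mol.length), *mol.extra_fields]
            fh.write("\t".join(zero) + "\n")
            one = ["1", *(_fmt(p) for p in mol.label_positions), _fmt(mol.length)]
            fh.write("\t".join(one) + "\n")
            for aux in mol.aux_lines:
                fh.write(aux + "\n")


def crop_bnx_molecule(molecule: BnxMolecule, start: float, length: float) -> BnxMolecule:
    """Digitally crop a molecule to the half-open window [start, start+length).

    Labels outside the window are deleted, the rest re-based to the window
    start; quality lines with one value per label are cropped in parallel,
    others dropped.  The cumulative window offset is recorded so the
    fragment's true placement within the parent stays known.
    """
    if start < 0 or length <= 0 or start + length > molecule.length + 1e-9:
        raise ValueError("crop window must lie within the molecule extent")
    keep = (molecule.label_positions >= start) & (molecule.label_positions < start + length)
    new_aux = []
    for aux in molecule.aux_lines:
        fields = aux.split("\t")
        if len(fields) == molecule.label_positions.size + 1:
            new_aux.append(
                "\t".join([fields[0]] + [f for f, k in zip(fields[1:], keep) if k])
            )
    return BnxMolecule(
        molecule_id=molecule.molecule_id,
        length=float(length),
        label_positions=molecule.label_positions[keep] - start,
        extra_fields=molecule.extra_fields,
        aux_lines=tuple(new_aux),
        crop_offset=molecule.crop_offset + start,
    )


def bnx_to_query_map(molecule: BnxMolecule, scale_bp_per_px: float = 335.0) -> QueryMap:
    """Convert native-unit BNX label positions to a pixel-unit query map."""
    pos = np.unique(molecule.label_positions) / scale_bp_per_px
    return QueryMap(
        positions_px=pos,
        molecule_id=molecule.molecule_id,
        molecule_length_px=molecule.length / scale_bp_per_px,
    )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_site_map(references: list[ReferenceMap], path: str | Path) -> None:
    rows = [
        {"sequence_id": ref.sequence_id, "position_bp": int(p)}
        for ref in references
        for p in ref.positions_bp
    ]
    pd.DataFrame(rows, columns=["sequence_id", "position_bp"]).to_csv(
        path, sep="\t", index=False
    )


def read_site_map(path: str | Path) -> list[ReferenceMap]:
    df = pd.read_csv(path, sep="\t")
    maps = []
    for seq_id, group in df.groupby("sequence_id", sort=False):
        maps.append(
            ReferenceMap(
                positions_bp=np.sort(group["position_bp"].to_numpy(dtype=np.float64)),
                sequence_id=str(seq_id),
            )
        )
    return maps


def write_query_maps(queries: list[QueryMap], path: str | Path) -> None:
    rows = [
        {"molecule_id": q.molecule_id, "position_px": p, "molecule_length_px": q.molecule_length_px}
        for q in queries
        for p in q.positions_px
    ]
    pd.DataFrame(rows, columns=["molecule_id", "position_px", "molecule_length_px"]).to_csv(
        path, sep="\t", index=False, float_format="%.4f"
    )


def read_query_maps(path: str | Path) -> list[QueryMap]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for mol_id, group in df.groupby("molecule_id", sort=False):
        out.append(
            QueryMap(
                positions_px=np.sort(group["position_px"].to_numpy(dtype=np.float64)),
                molecule_id=str(mol_id),
                molecule_length_px=float(group["molecule_length_px"].iloc[0]),
            )
        )
    return out
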