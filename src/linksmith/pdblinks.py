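"""PDB-header LINK records: parsing, the amino-amino exclusion filter, and
linkage-type tallies.

LINK lines follow PDB v3.3 fixed columns.  The refinement dialect LINKR
shares the atom/residue columns but carries the dictionary link-entry id in
the trailing field instead of a distance.  Peptide C-N pairs and SG-SG
cysteine pairs appearing in LINK records are backbone/disulfide artefacts
for survey purposes and are excluded before tallying.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .fixtures import builtin_amino_codes

log = logging.getLogger(__name__)


@dataclass
class PdbLinkRecord:
    atom1: str
    res1: str
    chain1: str
    seq1: Optional[int]
    atom2: str
    res2: str
    chain2: str
    seq2: Optional[int]
    distance: Optional[float] = None
    link_id: Optional[str] = None  # LINKR dialect
    source: str = ""               # originating file/entry id


def _int_or_none(s: str) -> Optional[int]:
    s = s.strip()
    return int(s) if s else None


def _atom_field(name: str) -> str:
    """PDB atom-name justification: single-letter elements start in the
    second column of the 4-character field."""
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}" if len(name) <= 3 else name


def format_link_record(atom1: str, res1: str, chain1: str, seq1: int,
                       atom2: str, res2: str, chain2: str, seq2: int,
                       distance: Optional[float] = None,
                       link_id: Optional[str] = None) -> str:
    """Compose a LINK (or, with ``link_id``, LINKR) line with correct
    fixed columns."""
    rec = "LINKR" if link_id else "LINK"
    line = (f"{rec:<6s}      {_atom_field(atom1)} {res1:>3s} {chain1:1s}"
            f"{seq1:4d}                {_atom_field(atom2)} {res2:>3s} "
            f"{chain2:1s}{seq2:4d}    1555   1555 ")
    if link_id:
        line += f"{link_id:>8s}"
    elif distance is not None:
        line += f"{distance:5.2f}"
    return line


def parse_link_records(text: str, source: str = "") -> list:
    """Parse LINK and LINKR lines; other lines are ignored and truncated
    records are skipped with a warning."""
    records = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("LINK  ", "LINKR ")):
            continue
        if len(line) < 57:
            log.warning("skipping truncated LINK record at line %d", lineno)
            continue
        is_linkr = line.startswith("LINKR")
        rec = PdbLinkRecord(
            atom1=line[12:16].strip(), res1=line[17:20].strip(),
            chain1=line[21:22].strip(), seq1=_int_or_none(line[22:26]),
            atom2=line[42:46].strip(), res2=line[47:50].strip(),
            chain2=line[51:52].strip(), seq2=_int_or_none(line[52:56]),
            source=source)
        if not (rec.atom1 and rec.res1 and rec.atom2 and rec.res2):
            log.warning("skipping incomplete LINK record at line %d", lineno)
            continue
        trailing = line[72:80].strip() if len(line) > 72 else ""
        if is_linkr:
            rec.link_id = trailing or None
        elif trailing:
            try:
                dist = float(line[73:78])
                rec.distance = dist if dist > 0 else None
            except ValueError:
                pass
        records.append(rec)
    return records


def filter_amino_amino(records: Iterable[PdbLinkRecord],
                       amino_codes: Optional[set] = None) -> list:
    """Keep records joining two amino acids, minus the known artefacts:
    backbone C-N pairs (in either order) and CYS SG-SG bridges."""
    codes = amino_codes if amino_codes is not None else builtin_amino_codes()
    out = []
    for rec in records:
        if rec.res1 not in codes or rec.res2 not in codes:
            continue
        if {rec.atom1, rec.atom2} == {"C", "N"}:
            continue
        if rec.res1 == "CYS" and rec.res2 == "CYS" \
                and rec.atom1 == "SG" and rec.atom2 == "SG":
            continue
        out.append(rec)
    return out


def canonical_type(rec: PdbLinkRecord) -> tuple:
    """Order-independent linkage type: the two (residue, atom) pairs sorted
    lexicographically."""
    ends = sorted([(rec.res1, rec.atom1), (rec.res2, rec.atom2)])
    return tuple(ends[0]) + tuple(ends[1])


def tally(records: Iterable[PdbLinkRecord]) -> pd.DataFrame:
    """Occurrences and distinct-source counts per canonical linkage type.

    Columns: res1, atom1, res2, atom2, n_files, n_total (sorted by
    descending total, then type)."""
    buckets = {}
    for rec in records:
        key = canonical_type(rec)
        total, files = buckets.get(key, (0, set()))
        files = files | ({rec.source} if rec.source else set())
        buckets[key] = (total + 1, files)
    rows = [
        {"res1": k[0], "atom1": k[1], "res2": k[2], "atom2": k[3],
         "n_files": len(v[1]), "n_total": v[0]}
        for k, v in buckets.items()]
    df = pd.DataFrame(rows, columns=["res1", "atom1", "res2", "atom2",
                                     "n_files", "n_total"])
    if len(df):
        df = df.sort_values(["n_total", "res1", "atom1", "res2", "atom2"],
                            ascending=[False, True, True, True, True]
                            ).reset_index(drop=True)
    return df


def tally_to_tsv(df: pd.DataFrame) -> str:
    return df.to_csv(sep="\t", index=False)
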