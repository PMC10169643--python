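"""Edge-list parsing, the indexed binary association matrix, and output writers.

The observed data is a set of (lncRNA, drug) resistance associations.  It is
held as a binary incidence matrix ``A`` (m lncRNAs x n drugs) with bijective
id <-> index maps.  Pairs absent from the input are *unknown* candidates, not
confirmed negatives; rows explicitly labelled 0 are kept separately as known
negatives so the negative sampler can prefer them.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence, TextIO

import numpy as np

from .errors import ContractError, IntegrityError, ParseError

__all__ = [
    "AssociationRecord",
    "AssociationMatrix",
    "parse_edge_list",
    "build_matrix",
    "write_predictions",
    "write_edge_list",
]


class AssociationRecord(NamedTuple):
    """One association assertion: a lncRNA, a drug, and a binary label.

    A missing label means the record states a known (positive) association.
    """

    lncrna_id: str
    drug_id: str
    label: int = 1


def _detect_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def parse_edge_list(source: TextIO | str, delimiter: str | None = None,
                    header: bool = False) -> list[AssociationRecord]:
    """Parse a delimited edge list into association records.

    Parameters
    ----------
    source
        Open text handle, or a string containing the delimited text.
    delimiter
        Field separator; autodetected (tab vs comma) from the first line
        when None.
    header
        If True the first non-empty line is skipped.

    Duplicate (lncrna, drug) pairs are deduplicated; duplicates with
    conflicting labels raise :class:`IntegrityError`.  Rows with a field
    count other than 2 or 3 raise :class:`ParseError` naming the line.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    lines = source.read().splitlines()
    content = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not content:
        return []
    if delimiter is None:
        delimiter = _detect_delimiter(content[0][1])
    if header:
        content = content[1:]

    records: list[AssociationRecord] = []
    seen: dict[tuple[str, str], int] = {}
    for lineno, line in content:
        fields = next(csv.reader([line], delimiter=delimiter))
        if len(fields) not in (2, 3):
            raise ParseError(
                f"line {lineno}: expected 2 or 3 fields, got {len(fields)}")
        lnc = fields[0].strip()
        drug = fields[1].strip()
        if not lnc or not drug:
            raise ParseError(f"line {lineno}: empty identifier")
        if len(fields) == 3:
            raw = fields[2].strip()
            if raw not in ("0", "1"):
                raise ParseError(
                    f"line {lineno}: label must be 0 or 1, got {raw!r}")
            label = int(raw)
        else:
            label = 1
        key = (lnc, drug)
        if key in seen:
            if seen[key] != label:
                raise IntegrityError(
                    f"line {lineno}: conflicting labels for pair {key}")
            continue
        seen[key] = label
        records.append(AssociationRecord(lnc, drug, label))
    return records


@dataclass
class AssociationMatrix:
    """Binary m x n lncRNA-by-drug incidence matrix with id maps."""

    A: np.ndarray
    lnc_ids: list[str]
    drug_ids: list[str]
    known_negatives: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=np.float64)
        if self.A.ndim != 2:
            raise ContractError("association matrix must be 2-D")
        if not np.isin(self.A, (0.0, 1.0)).all():
            raise ContractError("association matrix entries must be 0/1")
        if len(self.lnc_ids) != self.A.shape[0]:
            raise ContractError("lncRNA id count does not match row count")
        if len(self.drug_ids) != self.A.shape[1]:
            raise ContractError("drug id count does not match column count")

    @property
    def m(self) -> int:
        return self.A.shape[0]

    @property
    def n(self) -> int:
        return self.A.shape[1]

    @property
    def lnc_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.lnc_ids)}

    @property
    def drug_index(self) -> dict[str, int]:
        return {s: j for j, s in enumerate(self.drug_ids)}

    def positives(self) -> list[tuple[int, int]]:
        """Index pairs of known associations, in row-major order."""
        return [tuple(p) for p in np.argwhere(self.A == 1)]

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(self.A.copy(), list(self.lnc_ids),
                                 list(self.drug_ids), set(self.known_negatives))


def build_matrix(records: Sequence[AssociationRecord]) -> AssociationMatrix:
    """Assemble an :class:`AssociationMatrix` from parsed records.

    Rows (columns) are ordered by first appearance of each lncRNA (drug) id.
    ``A[i, j] = 1`` iff a positive record links them; explicitly 0-labelled
    pairs are retained in ``known_negatives``.
    """
    if not any(r.label == 1 for r in records):
        raise IntegrityError("edge list contains no positive association")
    lnc_ids: list[str] = []
    drug_ids: list[str] = []
    lnc_index: dict[str, int] = {}
    drug_index: dict[str, int] = {}
    for r in records:
        if r.lncrna_id not in lnc_index:
            lnc_index[r.lncrna_id] = len(lnc_ids)
            lnc_ids.append(r.lncrna_id)
        if r.drug_id not in drug_index:
            drug_index[r.drug_id] = len(drug_ids)
            drug_ids.append(r.drug_id)
    A = np.zeros((len(lnc_ids), len(drug_ids)))
    known_neg: set[tuple[int, int]] = set()
    for r in records:
        i, j = lnc_index[r.lncrna_id], drug_index[r.drug_id]
        if r.label == 1:
            A[i, j] = 1.0
        else:
            known_neg.add((i, j))
    return AssociationMatrix(A, lnc_ids, drug_ids, known_neg)


def write_predictions(scores: np.ndarray, matrix: AssociationMatrix,
                      sink: TextIO) -> None:
    """Write all (lncRNA, drug) pairs with score and known label as TSV.

    Rows are sorted by descending score; ties broken by (row, column) index.
    Scores are written with 10 significant digits so a write/parse round
    trip is faithful well past 6 digits.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != matrix.A.shape:
        raise ContractError(
            f"score shape {scores.shape} != matrix shape {matrix.A.shape}")
    order = sorted(
        ((i, j) for i in range(matrix.m) for j in range(matrix.n)),
        key=lambda ij: (-scores[ij], ij[0], ij[1]))
    sink.write("lncrna_id\tdrug_id\tscore\tknown_label\n")
    for i, j in order:
        sink.write(f"{matrix.lnc_ids[i]}\t{matrix.drug_ids[j]}\t"
                   f"{scores[i, j]:.10g}\t{int(matrix.A[i, j])}\n")


def write_edge_list(matrix: AssociationMatrix, sink: TextIO,
                    delimiter: str = "\t") -> None:
    """Write the positive pairs (and known negatives) back as an edge list."""
    for i, j in matrix.positives():
        sink.write(f"{matrix.lnc_ids[i]}{delimiter}{matrix.drug_ids[j]}"
                   f"{delimiter}1\n")
    for i, j in sorted(matrix.known_negatives):
        sink.write(f"{matrix.lnc_ids[i]}{delimiter}{matrix.drug_ids[j]}"
                   f"{delimiter}0\n")
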