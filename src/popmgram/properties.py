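"""Overlapping physicochemical property encoding of amino-acid residues.

The twenty standard residues are organised into ten *overlapping* groups
(Taylor's scheme): Polar, Positive, Negative, Charged, Hydrophobic,
Aliphatic, Aromatic, Small, Tiny and Proline.  A residue may belong to
several groups at once (lysine, for instance, is polar, positively
charged, charged and hydrophobic), so each residue is represented by a
10-bit membership vector rather than a one-hot code.  Stacking these row
vectors along a protein sequence yields the protein overlapping property
matrix (POPM), an ``L x 10`` binary matrix that is the input to the
tri-gram feature extractor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical ordering of the twenty standard one-letter residue codes.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Residue codes accepted but carrying no property information
#: (ambiguity codes and rare residues): encoded as the all-zero row.
NONSTANDARD_RESIDUES = frozenset("BJOUXZ")

N_PROPERTIES = 10

_DEFAULT_RESOURCE = "taylor_properties.tsv"


@dataclass(frozen=True)
class PropertyTable:
    """The ten overlapping property groups and the residue membership map.

    Attributes
    ----------
    groups:
        Ordered ``(name, residue frozenset)`` pairs.  The order fixes the
        meaning of column ``j`` of every POPM built from this table.
    version:
        Identifier of the grouping scheme (from the resource file header).
    """

    groups: tuple[tuple[str, frozenset[str]], ...]
    version: str = "unversioned"
    _membership: dict[str, np.ndarray] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        if len(self.groups) != N_PROPERTIES:
            raise ValueError(
                f"expected exactly {N_PROPERTIES} property groups, "
                f"got {len(self.groups)}"
            )
        membership: dict[str, np.ndarray] = {}
        for residue in STANDARD_RESIDUES:
            bits = np.fromiter(
                (int(residue in members) for _, members in self.groups),
                dtype=np.uint8,
                count=N_PROPERTIES,
            )
            if bits.sum() < 1:
                raise ValueError(
                    f"residue {residue!r} belongs to no property group"
                )
            bits.setflags(write=False)
            membership[residue] = bits
        object.__setattr__(self, "_membership", membership)

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.groups)

    def membership(self, residue: str) -> np.ndarray:
        """10-bit membership vector of a standard residue.

        Raises ``KeyError`` for anything but the 20 standard codes; use
        :func:`encode_residue` for the lenient variant.
        """
        return self._membership[residue.upper()]

    def membership_string(self, residue: str) -> str:
        """Membership vector rendered as a bit string, e.g. ``'0000110100'``."""
        return "".join(map(str, self.membership(residue)))


@dataclass(frozen=True)
class POPM:
    """Protein overlapping property matrix for a single sequence.

    ``matrix`` is an ``L x 10`` binary array; row ``i`` is the property
    membership vector of residue ``i`` (all-zero for non-standard codes).
    """

    matrix: np.ndarray
    sequence_id: str
    length: int

    def __post_init__(self) -> None:
        if self.matrix.shape != (self.length, N_PROPERTIES):
            raise ValueError(
                f"POPM shape {self.matrix.shape} inconsistent with "
                f"length {self.length}"
            )


def _parse_table(lines: list[str]) -> PropertyTable:
    version = "unversioned"
    groups: list[tuple[str, frozenset[str]]] = []
    for raw in lines:
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            version = line.lstrip("#").strip() or version
            continue
        name, _, residue_field = line.partition("\t")
        residues = frozenset(
            r.strip().upper() for r in residue_field.split(",") if r.strip()
        )
        if not name or not residues:
            raise ValueError(f"malformed property-table line: {raw!r}")
        groups.append((name, residues))
    return PropertyTable(groups=tuple(groups), version=version)


def build_property_table(path: str | Path | None = None) -> PropertyTable:
    """Load the property table (the packaged Taylor grouping by default).

    The on-disk format is one line per group — name, TAB, comma-separated
    residues — with an optional ``#`` version header, so alternative
    groupings can be swapped in.
    """
    if path is None:
        text = (
            resources.files("popmgram.data") / _DEFAULT_RESOURCE
        ).read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    return _parse_table(text.splitlines())


_DEFAULT_TABLE: PropertyTable | None = None


def default_property_table() -> PropertyTable:
    """The packaged Taylor table, loaded once per process."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = build_property_table()
    return _DEFAULT_TABLE


def encode_residue(
    residue: str, table: PropertyTable | None = None
) -> np.ndarray:
    """Encode one residue code as its 10-bit property vector.

    Standard residues map to their Taylor-group membership; recognised
    non-standard codes (B, J, O, U, X, Z) map to the all-zero vector with
    a logged warning, preserving sequence positions for the tri-gram
    window.  Non-alphabetic input raises ``ValueError``.
    """
    if len(residue) != 1 or not residue.isalpha():
        raise ValueError(
            f"residue must be a single alphabetic character, got {residue!r}"
        )
    table = table or default_property_table()
    upper = residue.upper()
    try:
        return table.membership(upper)
    except KeyError:
        logger.warning(
            "non-standard residue code %r encoded as all-zero vector", residue
        )
        return np.zeros(N_PROPERTIES, dtype=np.uint8)


def build_popm(
    sequence: str, sequence_id: str = "", table: PropertyTable | None = None
) -> POPM:
    """Build the ``L x 10`` POPM of a sequence.

    The sequence is case-folded to uppercase.  Empty or non-alphabetic
    input raises ``ValueError``; non-standard residue codes become
    all-zero rows (one aggregated warning per sequence).
    """
    if not sequence:
        raise ValueError(f"empty sequence (id={sequence_id!r})")
    if not sequence.isalpha():
        bad = sorted({c for c in sequence if not c.isalpha()})
        raise ValueError(
            f"sequence {sequence_id!r} contains non-alphabetic characters: {bad}"
        )
    table = table or default_property_table()
    seq = sequence.upper()
    nonstandard = sorted({c for c in seq if c not in table._membership})
    if nonstandard:
        logger.warning(
            "sequence %r: non-standard residues %s encoded as all-zero rows",
            sequence_id,
            nonstandard,
        )
    zero = np.zeros(N_PROPERTIES, dtype=np.uint8)
    matrix = np.stack(
        [table._membership.get(c, zero) for c in seq]
    ).astype(np.uint8)
    return POPM(matrix=matrix, sequence_id=sequence_id, length=len(seq))
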