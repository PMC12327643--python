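"""Residue alphabets, reduced-alphabet groupings and trigram vocabularies.

The full vocabulary over the 20 standard amino acids has 20**3 = 8000
trigram bins; a reduced alphabet with G groups has G**3 bins (1728 for the
12-group SDM12 scheme derived from structure-based substitution matrices).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

#: The 20 standard amino acids, in one-letter-code alphabetical order.
#: This order fixes the lexicographic trigram vocabulary order everywhere.
STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"

STANDARD_AA_SET = frozenset(STANDARD_AA)


@dataclass(frozen=True)
class AlphabetGrouping:
    """A partition of the 20 standard residues into named groups.

    Parameters
    ----------
    groups
        Mapping from group symbol to the string of member residues.
    name
        Identifier of the scheme (e.g. ``"SDM12"``).
    """

    groups: dict[str, str]
    name: str = "custom"

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for sym, members in self.groups.items():
            if len(sym) != 1:
                raise ValueError(f"group symbol {sym!r} must be one character")
            for res in members:
                if res not in STANDARD_AA_SET:
                    raise ValueError(f"group {sym!r} contains non-standard residue {res!r}")
                if res in seen:
                    raise ValueError(f"residue {res!r} assigned to groups {seen[res]!r} and {sym!r}")
                seen[res] = sym
        missing = STANDARD_AA_SET - set(seen)
        if missing:
            raise ValueError(f"grouping {self.name!r} does not cover residues: {sorted(missing)}")
        if len(self.groups) < 2:
            raise ValueError("a grouping needs at least 2 groups")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def alphabet(self) -> str:
        """Group symbols in sorted order; defines the reduced vocabulary order."""
        return "".join(sorted(self.groups))

    def residue_map(self) -> dict[str, str]:
        return {res: sym for sym, members in self.groups.items() for res in members}

    def apply(self, sequence: str) -> str:
        """Recode a standard-residue sequence into group symbols (same length)."""
        table = self.residue_map()
        try:
            return "".join(table[res] for res in sequence)
        except KeyError as exc:
            raise ValueError(f"residue {exc.args[0]!r} has no group in scheme {self.name!r}") from None


#: SDM12: 12 groups of amino acids clustered from structural substitution
#: matrices. Group symbols are the alphabetically-first member of each group.
SDM12 = AlphabetGrouping(
    groups={
        "A": "A",
        "C": "C",
        "D": "D",
        "G": "G",
        "H": "H",
        "K": "KER",
        "L": "LIVM",
        "N": "N",
        "P": "P",
        "T": "TSQ",
        "W": "W",
        "Y": "YF",
    },
    name="SDM12",
)


@dataclass(frozen=True)
class TrigramVocabulary:
    """Ordered vocabulary of all length-3 strings over an alphabet.

    Order is lexicographic in the alphabet's declared symbol order, so
    indices are portable across runs and machines.
    """

    alphabet: str
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError("alphabet symbols must be unique")
        trigrams = ["".join(t) for t in itertools.product(self.alphabet, repeat=3)]
        object.__setattr__(self, "_index", {t: i for i, t in enumerate(trigrams)})

    @property
    def size(self) -> int:
        return len(self.alphabet) ** 3

    @property
    def trigrams(self) -> list[str]:
        return list(self._index)

    def index(self, trigram: str) -> int:
        try:
            return self._index[trigram]
        except KeyError:
            raise KeyError(f"trigram {trigram!r} is outside the vocabulary") from None

    def __contains__(self, trigram: str) -> bool:
        return trigram in self._index

    def __len__(self) -> int:
        return self.size


def standard_vocabulary() -> TrigramVocabulary:
    """The 8000-bin vocabulary over the 20 standard amino acids."""
    return TrigramVocabulary(STANDARD_AA)


def reduced_vocabulary(grouping: AlphabetGrouping) -> TrigramVocabulary:
    """The G**3-bin vocabulary over a reduced alphabet (1728 for SDM12)."""
    return TrigramVocabulary(grouping.alphabet)
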