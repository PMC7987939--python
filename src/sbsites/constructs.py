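"""Transposon construct registry.

A construct carries the left and right transposon end sequences *as they
appear at the 5' of a junction read* (end sequence, then the target
dinucleotide, then genomic flank). The *end motif* is the short stretch
of the end immediately adjacent to the junction — the last
``motif_length`` bases of the end in read orientation — and is what the
flanking-sequence consensus of aberrant non-TA integrations is compared
against.

The classical Sleeping Beauty end reads ``...ACTG`` before the target
dinucleotide in this orientation; the IR/DR transition mutant used for
consensus-tracking experiments reads ``...ATCG`` (second and third motif
bases swapped from C,T to T,C). Full IR/DR end sequences are
configuration, not constants: the shipped presets carry synthetic 20 bp
end sequences whose terminal 4 bases are the documented motifs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import yaml

__all__ = [
    "TransposonConstruct",
    "ConstructRegistry",
    "mutate_end",
    "default_registry",
    "NATIVE_MOTIF",
    "MUTANT_MOTIF",
]

_DNA = frozenset("ACGT")

NATIVE_MOTIF = "ACTG"
MUTANT_MOTIF = "ATCG"

# Synthetic 20 bp end sequences for simulation: fixed arbitrary cores
# plus the junction-adjacent motif. Real IR/DR ends are supplied by the
# user through the registry file.
_LEFT_CORE = "CTGGAATCCGACGTCAACCG"[:16]
_RIGHT_CORE = "GGATCCGTTCAACGTGTCCA"[:16]


def _check_dna(seq: str, what: str) -> None:
    if not seq:
        raise ValueError(f"{what} must be a non-empty DNA string")
    if not _DNA.issuperset(seq):
        raise ValueError(f"{what} contains characters outside ACGT: {seq!r}")


@dataclass(frozen=True)
class TransposonConstruct:
    """Left/right end sequences plus the junction-adjacent end motif."""

    name: str
    left_end: str
    right_end: str
    motif_length: int = 4
    left_mutant: bool = False
    right_mutant: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("construct name must be non-empty")
        _check_dna(self.left_end, "left_end")
        _check_dna(self.right_end, "right_end")
        if self.motif_length < 2:
            raise ValueError("end motif length must be >= 2")
        if self.motif_length > min(len(self.left_end), len(self.right_end)):
            raise ValueError("motif length exceeds an end sequence")

    def end(self, side: str) -> str:
        if side == "left":
            return self.left_end
        if side == "right":
            return self.right_end
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")

    def motif(self, side: str = "left") -> str:
        """Junction-adjacent motif of an end: its last ``motif_length`` bases."""
        return self.end(side)[-self.motif_length :]

    @property
    def end_motif(self) -> str:
        """Motif used for consensus comparison (left end by convention)."""
        return self.motif("left")


def mutate_end(
    construct: TransposonConstruct,
    side: str,
    position: int,
    new_base: str,
    name: str | None = None,
) -> TransposonConstruct:
    """Return a new construct with one motif base substituted.

    ``position`` is 1-based within the end motif (position 1 is the
    motif's first base, kept unchanged in the canonical mutant designs
    because the terminal nucleotides are critical for transposition —
    mutating it raises a warning, not an error). The substitution is
    applied to the end sequence itself, so the re-derived motif reflects
    it; the input construct is unchanged.
    """
    if new_base not in _DNA:
        raise ValueError(f"new_base must be one of ACGT, got {new_base!r}")
    if not (1 <= position <= construct.motif_length):
        raise ValueError(
            f"position {position} outside motif (1..{construct.motif_length})"
        )
    if position == 1:
        warnings.warn(
            "mutating the first motif base: terminal end nucleotides are "
            "critical for transposition",
            stacklevel=2,
        )
    end = construct.end(side)
    idx = len(end) - construct.motif_length + (position - 1)
    new_end = end[:idx] + new_base + end[idx + 1 :]
    fields = {
        "name": name or f"{construct.name}_{side}{position}{new_base}",
        f"{side}_end": new_end,
        f"{side}_mutant": True,
    }
    return replace(construct, **fields)


class ConstructRegistry:
    """Named store of transposon constructs."""

    def __init__(self) -> None:
        self._constructs: dict[str, TransposonConstruct] = {}

    def register(
        self,
        name: str,
        left_end: str,
        right_end: str,
        motif_length: int = 4,
        left_mutant: bool = False,
        right_mutant: bool = False,
    ) -> TransposonConstruct:
        if name in self._constructs:
            raise ValueError(f"construct {name!r} already registered")
        construct = TransposonConstruct(
            name, left_end, right_end, motif_length, left_mutant, right_mutant
        )
        self._constructs[name] = construct
        return construct

    def add(self, construct: TransposonConstruct) -> TransposonConstruct:
        if construct.name in self._constructs:
            raise ValueError(f"construct {construct.name!r} already registered")
        self._constructs[construct.name] = construct
        return construct

    def get(self, name: str) -> TransposonConstruct:
        try:
            return self._constructs[name]
        except KeyError:
            raise KeyError(f"unknown construct {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._constructs

    def names(self) -> list[str]:
        return list(self._constructs)

    def save(self, path: str | Path) -> None:
        data = {
            name: {
                "left_end": c.left_end,
                "right_end": c.right_end,
                "motif_length": c.motif_length,
                "left_mutant": c.left_mutant,
                "right_mutant": c.right_mutant,
            }
            for name, c in self._constructs.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "ConstructRegistry":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        reg = cls()
        for name, fields in data.items():
            reg.register(
                name,
                fields["left_end"],
                fields["right_end"],
                motif_length=fields.get("motif_length", 4),
                left_mutant=fields.get("left_mutant", False),
                right_mutant=fields.get("right_mutant", False),
            )
        return reg


def default_registry() -> ConstructRegistry:
    """Registry preloaded with the standard construct presets.

    * ``pYT11`` — classical ends, motif ``ACTG`` on both sides.
    * ``pYT21`` — left end carrying the C,T→T,C transition motif ``ATCG``.
    * ``pYT22`` — right end mutated only; left stays native (``ACTG``).
    * ``pYT23`` — both ends mutated (motif ``ATCG``).
    * ``pYT53`` — left end with an A>T transversion at the second
      nucleotide of the end in transposon orientation, giving the
      read-orientation motif ``ACAG``; intended to be overridden from a
      registry file when a different orientation convention is wanted.
    """
    reg = ConstructRegistry()
    native_left = _LEFT_CORE + NATIVE_MOTIF
    native_right = _RIGHT_CORE + NATIVE_MOTIF
    mut_left = _LEFT_CORE + MUTANT_MOTIF
    mut_right = _RIGHT_CORE + MUTANT_MOTIF
    reg.register("pYT11", native_left, native_right)
    reg.register("pYT21", mut_left, native_right, left_mutant=True)
    reg.register("pYT22", native_left, mut_right, right_mutant=True)
    reg.register("pYT23", mut_left, mut_right, left_mutant=True, right_mutant=True)
    reg.register("pYT53", _LEFT_CORE + "ACAG", native_right, left_mutant=True)
    return reg
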