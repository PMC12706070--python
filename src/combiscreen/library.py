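"""Part libraries and combinatorial construct enumeration.

A *part* is one building block of a fusion activator: either an activation
domain (AD) or an inert, well-folding "protein folder" (PF) used as filler.
Each part carries a unique 8-nt DNA barcode; an ordered fusion of 1-3 parts
is a *construct*, identified by the dash-joined tuple of its part ids.
Position 1 is the position closest to the recruitment scaffold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BARCODE_LENGTH = 8
DNA = "ACGT"

#: control construct types built into the screen
CONTROL_TYPES = ("supernatant", "multi_copy", "mutant_scaffold")


@dataclass(frozen=True)
class Part:
    """One library building block."""

    part_id: str
    klass: str  # "AD" or "PF"
    inert: bool  # filler-eligible (inert PFs only)
    barcode: str
    sequence: str  # amino-acid sequence

    def __post_init__(self) -> None:
        if self.klass not in ("AD", "PF"):
            raise ValueError(f"klass must be 'AD' or 'PF', got {self.klass!r}")
        if len(self.barcode) != BARCODE_LENGTH:
            raise ValueError(
                f"barcode must be {BARCODE_LENGTH} nt, got {self.barcode!r}"
            )
        if set(self.barcode) - set(DNA):
            raise ValueError(f"barcode alphabet must be ACGT: {self.barcode!r}")
        if self.inert and self.klass != "PF":
            raise ValueError("only PF parts can be inert fillers")


@dataclass(frozen=True)
class Construct:
    """An ordered fusion of 1-3 parts (order matters: A-B != B-A)."""

    parts: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.parts) <= 3:
            raise ValueError(f"construct arity must be 1-3, got {len(self.parts)}")

    @property
    def construct_id(self) -> str:
        return "-".join(self.parts)

    @property
    def arity(self) -> int:
        return len(self.parts)

    def reverse(self) -> "Construct":
        return Construct(tuple(reversed(self.parts)))

    @property
    def is_palindromic(self) -> bool:
        return self.parts == tuple(reversed(self.parts))

    @classmethod
    def from_id(cls, construct_id: str) -> "Construct":
        return cls(tuple(construct_id.split("-")))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


def _random_barcodes(
    n: int, rng: np.random.Generator, length: int = BARCODE_LENGTH, min_dist: int = 3
) -> list[str]:
    """Draw n barcodes pairwise >= min_dist apart (rejection sampling).

    min_dist 3 guarantees that single-substitution correction is unambiguous.
    """
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        cand = "".join(rng.choice(list(DNA), size=length))
        if all(hamming(cand, b) >= min_dist for b in out):
            out.append(cand)
        attempts += 1
        if attempts > 100_000:  # pragma: no cover - generous for 8-mers
            raise RuntimeError("barcode sampling failed; lower min_dist or n")
    return out


# residue pools for synthetic AD / PF sequences; ADs are biased acidic and
# disorder-prone, mirroring the compositional signature of natural ADs
_AD_POOL = list("DDEEEEDLLFWYSTQNPGAMKR")
_PF_POOL = list("AVLIMFGTSKNEQYDRHW")


def _random_protein(length: int, pool: Sequence[str], rng: np.random.Generator) -> str:
    return "".join(rng.choice(pool, size=length))


@dataclass
class PartLibrary:
    """A set of parts plus reserved control barcodes."""

    parts: list[Part]
    control_barcodes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = [p.barcode for p in self.parts] + list(self.control_barcodes.values())
        if len(codes) != len(set(codes)):
            raise ValueError("barcodes must be unique within a library")

    def __iter__(self):
        return iter(self.parts)

    def __len__(self) -> int:
        return len(self.parts)

    @property
    def part_ids(self) -> list[str]:
        return [p.part_id for p in self.parts]

    @property
    def ads(self) -> list[Part]:
        return [p for p in self.parts if p.klass == "AD"]

    @property
    def fillers(self) -> list[Part]:
        """Inert PFs used to pad copy-number constructs."""
        return [p for p in self.parts if p.klass == "PF" and p.inert]

    def get(self, part_id: str) -> Part:
        for p in self.parts:
            if p.part_id == part_id:
                return p
        raise KeyError(part_id)

    def barcode_of(self, part_id: str) -> str:
        return self.get(part_id).barcode

    @classmethod
    def default(
        cls, n_ads: int = 22, n_pfs: int = 3, seed: int | np.random.Generator = 0
    ) -> "PartLibrary":
        """Build a synthetic screening library.

        Defaults mirror the screened design: 22 ADs plus 3 PFs of which two
        (the last and third-from-last) are inert filler-eligible, and three
        reserved control barcodes.
        """
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        n = n_ads + n_pfs
        barcodes = _random_barcodes(n + len(CONTROL_TYPES), rng)
        parts: list[Part] = []
        for i in range(n_ads):
            parts.append(
                Part(
                    part_id=f"A{i + 1:02d}",
                    klass="AD",
                    inert=False,
                    barcode=barcodes[i],
                    sequence=_random_protein(int(rng.integers(25, 61)), _AD_POOL, rng),
                )
            )
        for j in range(n_pfs):
            # with 3 PFs the middle one is a non-filler folder; the outer two
            # are the inert fillers used in copy-number analyses
            inert = n_pfs < 3 or j != 1
            parts.append(
                Part(
                    part_id=f"A{n_ads + j + 1:02d}",
                    klass="PF",
                    inert=inert,
                    barcode=barcodes[n_ads + j],
                    sequence=_random_protein(int(rng.integers(40, 81)), _PF_POOL, rng),
                )
            )
        controls = dict(zip(CONTROL_TYPES, barcodes[n:]))
        return cls(parts=parts, control_barcodes=controls)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "part_id": p.part_id,
                    "klass": p.klass,
                    "inert": p.inert,
                    "barcode": p.barcode,
                    "sequence": p.sequence,
                }
                for p in self.parts
            ]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, control_barcodes: dict[str, str] | None = None):
        parts = [
            Part(
                part_id=str(r.part_id),
                klass=str(r.klass),
                inert=bool(r.inert),
                barcode=str(r.barcode),
                sequence=str(r.sequence),
            )
            for r in df.itertuples()
        ]
        return cls(parts=parts, control_barcodes=control_barcodes or {})


def enumerate_constructs(parts: Iterable[Part | str], arity: int) -> list[Construct]:
    """All ordered tuples (with repetition) of the given parts.

    For p parts the result has p**arity members: 25 parts give 25 singles,
    625 bipartite and 15,625 tripartite fusions.
    """
    if arity not in (1, 2, 3):
        raise ValueError(f"arity must be 1, 2 or 3, got {arity}")
    ids = [p.part_id if isinstance(p, Part) else str(p) for p in parts]
    if not ids:
        raise ValueError("parts must be non-empty")
    return [Construct(t) for t in itertools.product(ids, repeat=arity)]


def construct_barcodes(construct: Construct, library: PartLibrary) -> tuple[str, ...]:
    """Barcode tuple of a construct in position order (position 1 first)."""
    return tuple(library.barcode_of(pid) for pid in construct.parts)
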