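"""Read parsing: scar-anchored barcode/UMI extraction and construct calling.

Amplicon reads carry, after an upstream anchor (the ORF-barcode cloning
scar), one (barcode, UMI) block per fusion position, separated by the
ligation scar left by successive cloning rounds. Because each new domain is
inserted between the previous ORF and its barcode, barcodes accumulate
innermost-last: the block read *last* belongs to position 1, the position
closest to the scaffold. Reads missing any expected feature are rejected
with a typed reason — rejections are data, not exceptions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .library import BARCODE_LENGTH, PartLibrary

#: rejection reasons emitted by parse_read / call_construct
REASONS = (
    "missing_anchor",
    "missing_scar",
    "wrong_block_length",
    "n_in_barcode",
    "unknown_barcode",
    "ambiguous",
)


@dataclass(frozen=True)
class ReadLayout:
    """Positions of barcode/UMI blocks within an amplicon read.

    The read is anchor + block + (scar + block) * (arity-1) + terminal,
    where block = 8-nt barcode + UMI. All offsets are 0-based half-open.
    """

    arity: int
    upstream_anchor: str = "TGTACG"
    scar: str = "CCTAGC"
    terminal: str = "CCTAGG"
    umi_length: int = 6
    block_order: str = "innermost_last"  # or "innermost_first"

    def __post_init__(self) -> None:
        if not self.upstream_anchor or not self.scar:
            raise ValueError("anchor and scar must be non-empty")
        if self.upstream_anchor == self.scar:
            raise ValueError("anchor and scar must be distinct")
        if self.block_order not in ("innermost_last", "innermost_first"):
            raise ValueError(f"unknown block_order {self.block_order!r}")

    @property
    def block_length(self) -> int:
        return BARCODE_LENGTH + self.umi_length

    @property
    def read_length(self) -> int:
        return (
            len(self.upstream_anchor)
            + self.arity * self.block_length
            + (self.arity - 1) * len(self.scar)
            + len(self.terminal)
        )

    def positions_to_read_order(self, items: tuple) -> tuple:
        """Reorder position-1-first items into the order they appear in a read."""
        return tuple(reversed(items)) if self.block_order == "innermost_last" else items

    def read_order_to_positions(self, items: tuple) -> tuple:
        return self.positions_to_read_order(items)  # reversal is an involution


@dataclass(frozen=True)
class ParsedRead:
    """Barcodes and UMIs in position order (position 1 first)."""

    barcodes: tuple[str, ...]
    umis: tuple[str, ...]

    @property
    def umi(self) -> str:
        """Clonal identifier: the position-1 (innermost) UMI."""
        return self.umis[0]


@dataclass(frozen=True)
class Rejection:
    reason: str


def encode_read(
    barcodes: tuple[str, ...],
    umis: tuple[str, ...],
    layout: ReadLayout,
) -> str:
    """Assemble a well-formed read; exact inverse of parse_read."""
    if len(barcodes) != layout.arity or len(umis) != layout.arity:
        raise ValueError("need one barcode and one UMI per position")
    blocks = [
        bc + u
        for bc, u in zip(
            layout.positions_to_read_order(barcodes),
            layout.positions_to_read_order(umis),
        )
    ]
    return layout.upstream_anchor + layout.scar.join(blocks) + layout.terminal


def parse_read(read: str, layout: ReadLayout) -> ParsedRead | Rejection:
    """Extract barcodes and UMIs from one read, or reject it.

    Anchor/scar matching is exact and case-insensitive, forward strand only.
    An N inside a barcode block rejects the read; an N inside a UMI is kept
    as a distinct symbol.
    """
    seq = read.upper()
    start = seq.find(layout.upstream_anchor.upper())
    if start < 0:
        return Rejection("missing_anchor")
    pos = start + len(layout.upstream_anchor)

    blocks: list[str] = []
    scar = layout.scar.upper()
    for i in range(layout.arity):
        block = seq[pos : pos + layout.block_length]
        if len(block) < layout.block_length:
            return Rejection("wrong_block_length")
        blocks.append(block)
        pos += layout.block_length
        if i < layout.arity - 1:
            if seq[pos : pos + len(scar)] != scar:
                return Rejection("missing_scar")
            pos += len(scar)

    barcodes = tuple(b[:BARCODE_LENGTH] for b in blocks)
    umis = tuple(b[BARCODE_LENGTH:] for b in blocks)
    if any("N" in bc for bc in barcodes):
        return Rejection("n_in_barcode")
    return ParsedRead(
        barcodes=layout.read_order_to_positions(barcodes),
        umis=layout.read_order_to_positions(umis),
    )


@dataclass
class BarcodeMap:
    """Injective barcode → part mapping plus labeled control barcodes."""

    parts: dict[str, str]  # barcode -> part_id
    controls: dict[str, str] = field(default_factory=dict)  # barcode -> control type

    def __post_init__(self) -> None:
        if len(set(self.parts.values())) != len(self.parts):
            raise ValueError("barcode->part mapping must be injective")
        if set(self.parts) & set(self.controls):
            raise ValueError("control barcodes must be disjoint from part barcodes")

    @classmethod
    def from_library(cls, library: PartLibrary) -> "BarcodeMap":
        return cls(
            parts={p.barcode: p.part_id for p in library},
            controls={bc: t for t, bc in library.control_barcodes.items()},
        )

    def lookup(self, barcode: str, max_mismatch: int = 0):
        """Return ('part'|'control', label) or a Rejection.

        With max_mismatch=1, a barcode is corrected to the unique known
        barcode within Hamming distance 1; two equidistant candidates make
        the read ambiguous.
        """
        if barcode in self.parts:
            return "part", self.parts[barcode]
        if barcode in self.controls:
            return "control", self.controls[barcode]
        if max_mismatch == 0:
            return Rejection("unknown_barcode")
        hits = []
        for known in list(self.parts) + list(self.controls):
            if sum(a != b for a, b in zip(known, barcode)) <= max_mismatch:
                hits.append(known)
        if not hits:
            return Rejection("unknown_barcode")
        if len(hits) > 1:
            return Rejection("ambiguous")
        known = hits[0]
        if known in self.parts:
            return "part", self.parts[known]
        return "control", self.controls[known]


@dataclass(frozen=True)
class ConstructCall:
    construct_id: str
    umi: str
    control_type: str | None = None

    @property
    def is_control(self) -> bool:
        return self.control_type is not None


def call_construct(
    parsed: ParsedRead, barcode_map: BarcodeMap, max_mismatch: int = 0
) -> ConstructCall | Rejection:
    """Resolve barcodes to a construct id, flagging control reads."""
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    part_ids: list[str] = []
    control: str | None = None
    for bc in parsed.barcodes:
        res = barcode_map.lookup(bc, max_mismatch=max_mismatch)
        if isinstance(res, Rejection):
            return res
        kind, label = res
        if kind == "control":
            control = label
        else:
            part_ids.append(label)
    if control is not None:
        return ConstructCall(
            construct_id=f"CTRL_{control}", umi=parsed.umi, control_type=control
        )
    return ConstructCall(construct_id="-".join(part_ids), umi=parsed.umi)


def tabulate_counts(
    calls: Iterable[ConstructCall],
    condition: str,
    replicate: int = 1,
    target: str = "target",
) -> pd.DataFrame:
    """Aggregate non-control calls into a UmiCountTable."""
    counter: Counter[tuple[str, str]] = Counter()
    for call in calls:
        if call.is_control:
            raise ValueError("control calls must be dropped before tabulation")
        counter[(call.construct_id, call.umi)] += 1
    rows = [
        {
            "construct_id": cid,
            "umi": umi,
            "condition": condition,
            "replicate": replicate,
            "target": target,
            "count": n,
        }
        for (cid, umi), n in sorted(counter.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["construct_id", "umi", "condition", "replicate", "target", "count"],
    )


@dataclass
class ExtractionResult:
    counts: pd.DataFrame
    rejections: dict[str, int]
    n_control: int
    n_accepted: int
    n_total: int

    def accounting_ok(self) -> bool:
        return self.n_accepted + self.n_control + sum(self.rejections.values()) == self.n_total


def extract_reads(
    reads: Iterable[str],
    layout: ReadLayout,
    barcode_map: BarcodeMap,
    condition: str = "unsorted",
    replicate: int = 1,
    target: str = "target",
    max_mismatch: int = 0,
) -> ExtractionResult:
    """Parse a read stream into counts plus a full rejection accounting."""
    rejections: Counter[str] = Counter()
    accepted: list[ConstructCall] = []
    n_control = 0
    n_total = 0
    for read in reads:
        n_total += 1
        parsed = parse_read(read, layout)
        if isinstance(parsed, Rejection):
            rejections[parsed.reason] += 1
            continue
        call = call_construct(parsed, barcode_map, max_mismatch=max_mismatch)
        if isinstance(call, Rejection):
            rejections[call.reason] += 1
            continue
        if call.is_control:
            n_control += 1
            continue
        accepted.append(call)
    counts = tabulate_counts(accepted, condition, replicate, target)
    return ExtractionResult(
        counts=counts,
        rejections=dict(rejections),
        n_control=n_control,
        n_accepted=len(accepted),
        n_total=n_total,
    )


def iter_fastq(path) -> Iterator[str]:
    """Yield sequences from an uncompressed single-end FASTQ file."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()  # +
            fh.readline()  # quality
            yield seq


def counts_to_reads(
    counts: pd.DataFrame,
    layout: ReadLayout,
    library: PartLibrary,
    rng: np.random.Generator,
) -> list[str]:
    """Emit one read per count from a UmiCountTable (lossless round trip).

    The clonal UMI occupies the position-1 block; outer blocks get random
    filler UMIs, as in the physical library where each cloning round added
    its own UMI.
    """
    bc_of = {p.part_id: p.barcode for p in library}
    reads: list[str] = []
    bases = np.array(list("ACGT"))
    for row in counts.itertuples():
        cid = row.construct_id
        if cid.startswith("CTRL_"):
            ctrl_type = cid[len("CTRL_") :]
            bcs = tuple([library.control_barcodes[ctrl_type]] * layout.arity)
        else:
            bcs = tuple(bc_of[p] for p in cid.split("-"))
        for _ in range(int(row.count)):
            fillers = [
                "".join(bases[rng.integers(0, 4, layout.umi_length)])
                for _ in range(layout.arity - 1)
            ]
            umis = (row.umi, *fillers)
            reads.append(encode_read(bcs, umis, layout))
    return reads


def write_fastq(reads: Iterable[str], path) -> int:
    """Write reads as plain single-end FASTQ with uniform quality."""
    n = 0
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@read{i}\n{read}\n+\n{'I' * len(read)}\n")
            n += 1
    return n
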