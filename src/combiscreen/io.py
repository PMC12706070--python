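"""Plain-TSV interchange between pipeline stages.

Every stage reads and writes headered TSV so intermediates are inspectable
and language-neutral; FASTQ appears only at the simulate/extract boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .library import PartLibrary
from .simulate import ScreenSimulation


def write_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"construct_id": str, "umi": str, "condition": str, "target": str},
    )
    df["count"] = df["count"].astype(int)
    return df


def write_parts_tsv(library: PartLibrary, path) -> Path:
    return write_tsv(library.to_frame(), path)


def read_parts_tsv(path, controls_path=None) -> PartLibrary:
    controls = None
    if controls_path is not None:
        controls = {
            str(r.control_type): str(r.barcode)
            for r in pd.read_csv(controls_path, sep="\t").itertuples()
        }
    return PartLibrary.from_frame(pd.read_csv(path, sep="\t"), controls)


def write_controls_tsv(library: PartLibrary, path) -> Path:
    df = pd.DataFrame(
        [
            {"control_type": t, "barcode": bc}
            for t, bc in library.control_barcodes.items()
        ]
    )
    return write_tsv(df, path)


def write_simulation(sim: ScreenSimulation, outdir) -> dict[str, str]:
    """Emit all fixture tables for one simulated screen; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "parts": write_parts_tsv(sim.library, outdir / "parts.tsv"),
        "controls": write_controls_tsv(sim.library, outdir / "controls.tsv"),
        "constructs": write_tsv(
            pd.DataFrame({"construct_id": [c.construct_id for c in sim.constructs]}),
            outdir / "constructs.tsv",
        ),
        "latent": write_tsv(sim.truth, outdir / "latent_params.tsv"),
        "counts": write_tsv(sim.counts, outdir / "counts.tsv"),
        "mfi": write_tsv(sim.mfi, outdir / "bin_mfi.tsv"),
        "plasmid": write_tsv(sim.plasmid_abundances, outdir / "plasmid_abundances.tsv"),
    }
    return {k: str(v) for k, v in paths.items()}


def write_manifest(path, **fields) -> Path:
    """Record config, seed and version so a run can be reproduced exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
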