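"""Synthetic combinatorial sort-seq screen generator.

Emulates the full physical pipeline with known ground truth: a barcoded
combinatorial plasmid library is lentivirally transduced at low MOI into a
cell population, toxic constructs deplete over passaging, the population is
FACS-sorted into four extreme expression bins (two low, two high, 12.5% of
cells each), and barcode/UMI amplicons are sequenced per bin, per the
unsorted population, and per the plasmid pool.

Every latent parameter (per-part activation strength, per-part fitness cost,
pairwise interactions) is recorded so downstream scoring can be validated
against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .library import CONTROL_TYPES, Construct, PartLibrary, enumerate_constructs

#: schema of the long count table shared across the whole pipeline
COUNT_COLUMNS = ["construct_id", "umi", "condition", "replicate", "target", "count"]
BIN_CONDITIONS = ["bin1", "bin2", "bin3", "bin4"]

#: control pseudo-construct ids as they appear in simulator tables
CONTROL_IDS = {t: f"CTRL_{t}" for t in CONTROL_TYPES}

_BASES = np.array(list("ACGT"))


def is_control_id(construct_id: str) -> bool:
    return construct_id.startswith("CTRL_")


def drop_controls(table: pd.DataFrame) -> pd.DataFrame:
    """Remove control pseudo-construct rows before scoring."""
    mask = table["construct_id"].str.startswith("CTRL_")
    return table.loc[~mask].reset_index(drop=True)


@dataclass
class SimConfig:
    """Study-condition knobs for a synthetic screen.

    Defaults follow the screened design: MOI 0.1, four 12.5% extreme sort
    gates, 6-nt UMIs, three passages under selection, and control constructs
    spiked at ~3.6% (single-domain) or ~1.5% (bi-/tripartite) each.
    """

    n_ads: int = 22
    n_pfs: int = 3
    arity: int = 2
    moi: float = 0.1
    n_cells: int = 1_000_000
    passages: int = 3
    umi_length: int = 6
    bin_fractions: tuple[float, float, float, float] = (0.125, 0.125, 0.125, 0.125)
    read_depth: int = 1_000_000
    jackpot_prob: float = 0.01
    jackpot_factor: float = 10.0
    control_fractions: dict[str, float] | None = None
    targets: tuple[str, ...] = ("EPCAM", "CXCR4")
    n_replicates: int = 2
    multi_copy: bool = False
    plasmid_umis: int = 32
    supernatant_attenuation: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arity not in (1, 2, 3):
            raise ValueError("arity must be 1, 2 or 3")
        if len(self.bin_fractions) != 4:
            raise ValueError("exactly four sort bins are required")
        if sum(self.bin_fractions) > 1 + 1e-12:
            raise ValueError("bin fractions must sum to <= 1")
        if self.control_fractions is None:
            f = 0.036 if self.arity == 1 else 0.015
            self.control_fractions = {t: f for t in CONTROL_TYPES}


@dataclass
class LatentParams:
    """Ground-truth generative parameters.

    base_strength: per-part fluorescence contribution (arbitrary units;
    inert PFs are 0). fitness_cost: per-part per-passage log2 growth deficit;
    a construct's cost is the sum of its parts' costs. interactions: optional
    additive term per adjacent part pair; with order_sensitivity the term is
    keyed on the ordered pair, otherwise on the unordered pair.
    """

    base_strength: dict[str, float]
    fitness_cost: dict[str, float]
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 0.3
    order_sensitivity: bool = False
    baseline: float = 1.0

    @classmethod
    def random(
        cls,
        library: PartLibrary,
        rng: np.random.Generator,
        strength_sigma: float = 1.0,
        cost_max: float = 0.4,
        noise_sd: float = 0.3,
    ) -> "LatentParams":
        strength: dict[str, float] = {}
        cost: dict[str, float] = {}
        for p in library:
            if p.klass == "AD":
                strength[p.part_id] = float(rng.lognormal(0.0, strength_sigma))
                cost[p.part_id] = float(rng.uniform(0.0, cost_max))
            else:
                strength[p.part_id] = 0.0
                cost[p.part_id] = 0.0
        return cls(base_strength=strength, fitness_cost=cost, noise_sd=noise_sd)

    def strength_of(self, parts: tuple[str, ...]) -> float:
        s = sum(self.base_strength[p] for p in parts)
        for a, b in zip(parts, parts[1:]):
            key = (a, b) if self.order_sensitivity else tuple(sorted((a, b)))
            s += self.interactions.get(key, 0.0)
        return max(s, 0.0)

    def cost_of(self, parts: tuple[str, ...]) -> float:
        return sum(self.fitness_cost[p] for p in parts)

    def truth_frame(self, constructs: list[Construct]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "construct_id": [c.construct_id for c in constructs],
                "strength": [self.strength_of(c.parts) for c in constructs],
                "fitness_cost": [self.cost_of(c.parts) for c in constructs],
            }
        )


def _random_umis(n: int, length: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.integers(0, 4, size=(n, length))
    return np.array(["".join(row) for row in _BASES[idx]])


def simulate_cell_pool(
    constructs: list[Construct],
    plasmid_abundances: np.ndarray,
    config: SimConfig,
    latent: LatentParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Transduce, select and passage a cell population.

    Integration counts are Poisson(moi) per cell; an infected cell keeps one
    construct drawn proportional to plasmid abundance (single-copy default).
    Each transduction event receives a fresh random UMI. Growth then scales
    each clone by 2**(-fitness_cost * passages).

    Returns a frame (construct_id, umi, cell_count) with real-valued counts.
    """
    abund = np.asarray(plasmid_abundances, dtype=float)
    if abund.shape != (len(constructs),):
        raise ValueError("one abundance per construct required")
    if (abund < 0).any() or abund.sum() <= 0:
        raise ValueError("plasmid abundances must be >= 0 with a positive sum")

    p_infected = 1.0 - np.exp(-config.moi)
    n_infected = int(rng.binomial(config.n_cells, p_infected))
    if n_infected == 0:
        raise ValueError("no cells infected; raise moi or n_cells")

    choice = rng.choice(len(constructs), size=n_infected, p=abund / abund.sum())
    umis = _random_umis(n_infected, config.umi_length, rng)
    ids = np.array([c.construct_id for c in constructs])
    pool = (
        pd.DataFrame({"construct_id": ids[choice], "umi": umis})
        .groupby(["construct_id", "umi"], sort=True)
        .size()
        .rename("cell_count")
        .astype(float)
        .reset_index()
    )

    cost = {c.construct_id: latent.cost_of(c.parts) for c in constructs}
    depletion = np.power(
        2.0, -pool["construct_id"].map(cost).to_numpy() * config.passages
    )
    pool["cell_count"] *= depletion
    return pool


def simulate_sort(
    cells: pd.DataFrame,
    latent: LatentParams,
    config: SimConfig,
    rng: np.random.Generator,
    strengths: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """FACS-sort a population into four extreme bins.

    Per-cell fluorescence is log-normal around baseline + summed part
    strengths; cells are ranked (ties broken by construct_id then UMI for
    determinism) and gated at the 0-12.5, 12.5-25, 75-87.5 and 87.5-100
    population percentiles.

    Returns (binned cells frame with columns construct_id/umi/bin/cell_count,
    per-bin mean fluorescence vector).
    """
    weights = cells["cell_count"].to_numpy(dtype=float)
    total = int(round(weights.sum()))
    if total < 8:
        raise ValueError("at least 8 cells are required to sort four bins")
    counts = rng.multinomial(total, weights / weights.sum())
    row_idx = np.repeat(np.arange(len(cells)), counts)

    if strengths is None:
        strengths = {
            cid: latent.strength_of(Construct.from_id(cid).parts)
            for cid in cells["construct_id"].unique()
        }
    s = cells["construct_id"].map(strengths).to_numpy(dtype=float)[row_idx]
    log_fluor = np.log(latent.baseline + s)
    if latent.noise_sd > 0:
        log_fluor = log_fluor + rng.normal(0.0, latent.noise_sd, size=len(row_idx))
    fluor = np.exp(log_fluor)

    cid_codes = pd.factorize(cells["construct_id"], sort=True)[0][row_idx]
    umi_codes = pd.factorize(cells["umi"], sort=True)[0][row_idx]
    order = np.lexsort((umi_codes, cid_codes, fluor))

    n = len(order)
    sizes = [int(np.floor(n * f)) for f in config.bin_fractions]
    slices = [
        slice(0, sizes[0]),
        slice(sizes[0], sizes[0] + sizes[1]),
        slice(n - sizes[3] - sizes[2], n - sizes[3]),
        slice(n - sizes[3], n),
    ]

    frames = []
    mfi = np.empty(4)
    for b, sl in enumerate(slices):
        members = order[sl]
        mfi[b] = float(fluor[members].mean())
        binned = (
            pd.DataFrame(
                {
                    "construct_id": cells["construct_id"].to_numpy()[row_idx[members]],
                    "umi": cells["umi"].to_numpy()[row_idx[members]],
                }
            )
            .groupby(["construct_id", "umi"], sort=True)
            .size()
            .rename("cell_count")
            .reset_index()
        )
        binned.insert(2, "bin", BIN_CONDITIONS[b])
        frames.append(binned)
    return pd.concat(frames, ignore_index=True), mfi


def simulate_sequencing(
    condition_weights: dict[str, pd.DataFrame],
    config: SimConfig,
    rng: np.random.Generator,
    jackpot_conditions: set[str] | None = None,
) -> pd.DataFrame:
    """Draw sequencing reads per condition.

    Each condition frame has columns (construct_id, umi, weight); reads are
    multinomial over rows proportional to weight. In cell-derived conditions
    each (construct, UMI) is independently PCR-jackpotted with probability
    jackpot_prob, multiplying its reads by jackpot_factor — the artifact the
    outlier-UMI filter is designed to remove.
    """
    if config.read_depth <= 0:
        raise ValueError("read_depth must be positive")
    if jackpot_conditions is None:
        jackpot_conditions = set(condition_weights) - {"plasmid"}

    out = []
    for condition, frame in condition_weights.items():
        w = frame["weight"].to_numpy(dtype=float)
        if w.sum() <= 0:
            continue
        reads = rng.multinomial(config.read_depth, w / w.sum())
        if condition in jackpot_conditions and config.jackpot_prob > 0:
            hit = rng.random(len(reads)) < config.jackpot_prob
            reads = np.where(
                hit, np.round(reads * config.jackpot_factor).astype(int), reads
            )
        keep = reads > 0
        out.append(
            pd.DataFrame(
                {
                    "construct_id": frame["construct_id"].to_numpy()[keep],
                    "umi": frame["umi"].to_numpy()[keep],
                    "condition": condition,
                    "count": reads[keep],
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=["construct_id", "umi", "condition", "count"])
    return pd.concat(out, ignore_index=True)


@dataclass
class ScreenSimulation:
    """Everything a downstream stage (or a test) needs about one screen."""

    config: SimConfig
    library: PartLibrary
    constructs: list[Construct]
    latent: LatentParams
    truth: pd.DataFrame  # per-construct latent strength and fitness cost
    counts: pd.DataFrame  # UmiCountTable across conditions/replicates/targets
    mfi: pd.DataFrame  # per (target, replicate, bin) mean fluorescence
    plasmid_abundances: pd.DataFrame  # per-construct plasmid fractions


def _plasmid_umi_weights(
    ids: np.ndarray,
    weights: np.ndarray,
    n_umis: int,
    umi_length: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Spread plasmid construct weight over per-construct random UMIs.

    Plasmid pools carry enormous clonal UMI diversity (each bacterial colony
    its own UMI), so no single UMI dominates — which is why the outlier-UMI
    filter is not applied to plasmid counts downstream.
    """
    rep_ids = np.repeat(ids, n_umis)
    rep_w = np.repeat(weights / n_umis, n_umis)
    umis = _random_umis(len(rep_ids), umi_length, rng)
    return pd.DataFrame({"construct_id": rep_ids, "umi": umis, "weight": rep_w})


def simulate_screen(
    config: SimConfig,
    library: PartLibrary | None = None,
    latent: LatentParams | None = None,
) -> ScreenSimulation:
    """Run a full synthetic screen: library → cells → sort → sequencing.

    One independent transduction/sort/sequencing chain is simulated per
    (target, replicate); the plasmid pool is shared. Control constructs are
    spiked into the plasmid at their configured fractions: the supernatant
    control is never packaged into cells but contaminates sequencing of
    cell-derived conditions at an attenuated rate; the multi-copy control
    rides along in co-infected cells (emulated with a random co-occupant
    strength); the mutant-scaffold control behaves as a zero-strength
    construct.
    """
    rng = np.random.default_rng(config.seed)
    if library is None:
        library = PartLibrary.default(config.n_ads, config.n_pfs, seed=rng)
    if latent is None:
        latent = LatentParams.random(library, rng)

    constructs = enumerate_constructs(library.parts, config.arity)
    truth = latent.truth_frame(constructs)

    # plasmid pool: log-normal member abundances plus control spikes
    member_w = rng.lognormal(0.0, 0.25, size=len(constructs))
    member_w /= member_w.sum()
    ctrl_fracs = config.control_fractions or {}
    lib_frac = 1.0 - sum(ctrl_fracs.values())
    ids = [c.construct_id for c in constructs] + [
        CONTROL_IDS[t] for t in ctrl_fracs
    ]
    plasmid_w = np.concatenate(
        [member_w * lib_frac, np.array([ctrl_fracs[t] for t in ctrl_fracs])]
    )
    plasmid = pd.DataFrame({"construct_id": ids, "fraction": plasmid_w})

    # constructs as transduced into cells: supernatant control is unpackaged
    cell_constructs = list(constructs)
    cell_w = list(member_w * lib_frac)
    strengths = {c.construct_id: latent.strength_of(c.parts) for c in constructs}
    costs = dict(zip(truth["construct_id"], truth["fitness_cost"]))
    for t, frac in ctrl_fracs.items():
        if t == "supernatant":
            continue
        cid = CONTROL_IDS[t]
        cell_constructs.append(_ControlConstruct(cid))
        cell_w.append(frac)
        costs[cid] = 0.0
        if t == "mutant_scaffold":
            strengths[cid] = 0.0
        else:  # multi_copy: fluorescence follows a random co-occupant
            strengths[cid] = strengths[
                constructs[int(rng.integers(len(constructs)))].construct_id
            ]

    latent_cells = replace(
        latent,
        base_strength=dict(latent.base_strength),
        fitness_cost=dict(latent.fitness_cost),
    )

    counts_frames = []
    mfi_rows = []
    for target in config.targets:
        for rep in range(1, config.n_replicates + 1):
            pool = _simulate_pool_with_controls(
                cell_constructs, np.array(cell_w), costs, config, rng
            )
            binned, mfi = simulate_sort(
                pool, latent_cells, config, rng, strengths=strengths
            )
            cond_weights: dict[str, pd.DataFrame] = {}
            for b in BIN_CONDITIONS:
                sub = binned.loc[binned["bin"] == b, ["construct_id", "umi"]].copy()
                sub["weight"] = binned.loc[binned["bin"] == b, "cell_count"].to_numpy()
                cond_weights[b] = sub
            unsorted = pool.rename(columns={"cell_count": "weight"})
            cond_weights["unsorted"] = unsorted
            cond_weights["plasmid"] = _plasmid_umi_weights(
                plasmid["construct_id"].to_numpy(),
                plasmid["fraction"].to_numpy(),
                config.plasmid_umis,
                config.umi_length,
                rng,
            )
            table = simulate_sequencing(cond_weights, config, rng)

            # unpackaged supernatant plasmid contaminates cell-derived reads
            sup_frac = ctrl_fracs.get("supernatant", 0.0)
            if sup_frac > 0:
                n_sup = int(
                    round(config.read_depth * sup_frac * config.supernatant_attenuation)
                )
                if n_sup > 0:
                    sup_umis = _random_umis(
                        min(n_sup, config.plasmid_umis), config.umi_length, rng
                    )
                    per = rng.multinomial(n_sup, np.ones(len(sup_umis)) / len(sup_umis))
                    extra = pd.DataFrame(
                        {
                            "construct_id": CONTROL_IDS["supernatant"],
                            "umi": sup_umis[per > 0],
                            "condition": "unsorted",
                            "count": per[per > 0],
                        }
                    )
                    table = pd.concat([table, extra], ignore_index=True)

            table["replicate"] = rep
            table["target"] = target
            counts_frames.append(table[COUNT_COLUMNS])
            for b, v in zip(BIN_CONDITIONS, mfi):
                mfi_rows.append(
                    {"target": target, "replicate": rep, "bin": b, "mfi": v}
                )

    counts = pd.concat(counts_frames, ignore_index=True)
    mfi_df = pd.DataFrame(mfi_rows)
    return ScreenSimulation(
        config=config,
        library=library,
        constructs=constructs,
        latent=latent,
        truth=truth,
        counts=counts,
        mfi=mfi_df,
        plasmid_abundances=plasmid,
    )


class _ControlConstruct:
    """Duck-typed stand-in so control spikes flow through pool simulation."""

    def __init__(self, construct_id: str):
        self.construct_id = construct_id
        self.parts: tuple[str, ...] = ()


def _simulate_pool_with_controls(
    constructs: list,
    abundances: np.ndarray,
    costs: dict[str, float],
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """simulate_cell_pool generalized to pseudo-constructs with known costs."""
    if (abundances < 0).any() or abundances.sum() <= 0:
        raise ValueError("plasmid abundances must be >= 0 with a positive sum")
    p_infected = 1.0 - np.exp(-config.moi)
    n_infected = int(rng.binomial(config.n_cells, p_infected))
    choice = rng.choice(len(constructs), size=n_infected, p=abundances / abundances.sum())
    umis = _random_umis(n_infected, config.umi_length, rng)
    ids = np.array([c.construct_id for c in constructs])
    pool = (
        pd.DataFrame({"construct_id": ids[choice], "umi": umis})
        .groupby(["construct_id", "umi"], sort=True)
        .size()
        .rename("cell_count")
        .astype(float)
        .reset_index()
    )
    depletion = np.power(
        2.0, -pool["construct_id"].map(costs).to_numpy() * config.passages
    )
    pool["cell_count"] *= depletion
    return pool
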