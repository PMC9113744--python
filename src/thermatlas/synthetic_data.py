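"""Multi-tissue, multi-temperature count simulator with planted ground truth.

The generator mirrors the design of a mouse thermal-adaptation experiment:
several tissues sampled at a control housing temperature (22 degC) and at one
or two treatment temperatures (cold 10 degC and/or mild warm 34 degC), with
each sequenced sample being a pool of ``pool_size`` animals.  Counts are drawn
per animal from a negative binomial with gene x tissue specific baseline
expression and a planted log2 fold change at treatment temperatures, then
summed over the pool.  A :class:`SimTruth` table records the true role and
effect of every gene so downstream stages can be scored against ground truth.

Baseline expression: each gene has a shared log2-mean drawn uniformly from
``baseline_logmean_range`` plus a per-tissue normal offset
(``tissue_offset_sd``), so most genes are expressed in every tissue while a
configurable fraction is made strictly tissue-exclusive (baseline 0 outside
one tissue), matching the bulk structure observed in multi-tissue atlases
(a majority of genes detected in all tissues, a small minority exclusive).

Randomness: one root seed; per-tissue child streams are derived with
``numpy.random.SeedSequence`` so adding tissues never perturbs the draws of
existing ones.  A fixed seed yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CountMatrix

__all__ = [
    "SimConfigError",
    "PlantedSignal",
    "SimConfig",
    "SimTruth",
    "simulate_experiment",
    "simulate_null",
    "standard_planting",
    "make_toy_fixture",
    "TOY_SEED",
]

ROLES = (
    "null",
    "tissue_specific_up",
    "tissue_specific_down",
    "shared_up",
    "shared_down",
    "inverse",
)

CONTROL_TEMPERATURE = 22.0


class SimConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class PlantedSignal:
    """A gene with a known, non-null regulatory role.

    ``log2fc_by_temperature`` maps each treatment temperature to the true
    log2 fold change applied there, relative to the 22 degC control.  The
    ``inverse`` role requires opposite signs at the two non-control
    temperatures; ``tissue_specific_*`` roles require exactly one target
    tissue.
    """

    gene_id: str
    role: str
    target_tissues: tuple[str, ...]
    log2fc_by_temperature: Mapping[float, float]

    def __post_init__(self) -> None:
        if self.role not in ROLES or self.role == "null":
            raise SimConfigError(f"invalid planted role {self.role!r}")
        object.__setattr__(self, "target_tissues", tuple(self.target_tissues))
        object.__setattr__(
            self,
            "log2fc_by_temperature",
            {float(k): float(v) for k, v in dict(self.log2fc_by_temperature).items()},
        )
        if self.role.startswith("tissue_specific") and len(self.target_tissues) != 1:
            raise SimConfigError(
                f"{self.gene_id}: tissue_specific role needs exactly one target tissue"
            )
        if self.role == "inverse":
            fcs = [v for v in self.log2fc_by_temperature.values()]
            if len(fcs) != 2 or fcs[0] * fcs[1] >= 0:
                raise SimConfigError(
                    f"{self.gene_id}: inverse role needs opposite-sign log2FC at the "
                    "two non-control temperatures"
                )
        sign = {"tissue_specific_up": 1, "shared_up": 1,
                "tissue_specific_down": -1, "shared_down": -1}.get(self.role)
        if sign is not None:
            for t, v in self.log2fc_by_temperature.items():
                if v * sign <= 0:
                    raise SimConfigError(
                        f"{self.gene_id}: role {self.role} requires log2FC of sign "
                        f"{sign} at temperature {t}"
                    )


@dataclass(frozen=True)
class SimConfig:
    n_tissues: int = 11
    n_genes: int = 2000
    temperatures: tuple[float, ...] = (10.0, 22.0, 34.0)
    n_samples_per_group: int = 3
    pool_size: int = 2
    dispersion: float = 0.1
    baseline_logmean_range: tuple[float, float] = (3.0, 7.0)
    tissue_offset_sd: float = 0.8
    frac_tissue_exclusive: float = 0.08
    planted: tuple[PlantedSignal, ...] = ()
    lib_size_mean: int = 600_000
    lib_size_cv: float = 0.2
    mass_balance: bool = True
    seed: int = 0
    tissues: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 2:
            raise SimConfigError("n_samples_per_group must be >= 2")
        if self.dispersion < 0:
            raise SimConfigError("dispersion must be > 0 (use ~0 for Poisson)")
        if not 0 <= self.frac_tissue_exclusive <= 1:
            raise SimConfigError("frac_tissue_exclusive must be in [0, 1]")
        if self.lib_size_mean <= 0:
            raise SimConfigError("lib_size_mean must be positive")
        if CONTROL_TEMPERATURE not in [float(t) for t in self.temperatures]:
            raise SimConfigError("temperatures must include the 22 degC control")
        object.__setattr__(self, "temperatures", tuple(float(t) for t in self.temperatures))
        object.__setattr__(self, "planted", tuple(self.planted))
        if self.tissues is None:
            object.__setattr__(
                self, "tissues", tuple(f"tissue{i + 1:02d}" for i in range(self.n_tissues))
            )
        else:
            object.__setattr__(self, "tissues", tuple(self.tissues))
            if len(self.tissues) != self.n_tissues:
                raise SimConfigError("len(tissues) must equal n_tissues")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i + 1:0{width}d}" for i in range(self.n_genes)]

    @property
    def treatment_temperatures(self) -> tuple[float, ...]:
        return tuple(t for t in self.temperatures if t != CONTROL_TEMPERATURE)


@dataclass
class SimTruth:
    """Planted role and true effect of every gene x tissue x temperature."""

    table: pd.DataFrame  # columns: gene, tissue, temperature_c, true_log2fc, role

    def roles(self) -> pd.Series:
        """Global role label per gene."""
        return self.table.groupby("gene")["role"].first()

    def true_log2fc(self, tissue: str, temperature: float) -> pd.Series:
        sub = self.table[
            (self.table["tissue"] == tissue)
            & (self.table["temperature_c"] == float(temperature))
        ]
        return sub.set_index("gene")["true_log2fc"]


def _validate_planted(config: SimConfig) -> None:
    known = set(config.gene_ids)
    seen: set[str] = set()
    for sig in config.planted:
        if sig.gene_id not in known:
            raise SimConfigError(f"planted gene {sig.gene_id!r} not among simulated genes")
        if sig.gene_id in seen:
            raise SimConfigError(f"gene {sig.gene_id!r} planted twice")
        seen.add(sig.gene_id)
        for t in sig.target_tissues:
            if t not in config.tissues:
                raise SimConfigError(f"planted tissue {t!r} not among simulated tissues")
        for temp in sig.log2fc_by_temperature:
            if temp not in config.treatment_temperatures:
                raise SimConfigError(
                    f"{sig.gene_id}: planted temperature {temp} is not a treatment "
                    "temperature"
                )


def _true_log2fc_matrix(config: SimConfig) -> dict[tuple[str, float], np.ndarray]:
    """Per (tissue, treatment temperature): vector of true log2FC over genes."""
    gene_index = {g: i for i, g in enumerate(config.gene_ids)}
    out = {
        (tis, temp): np.zeros(config.n_genes)
        for tis in config.tissues
        for temp in config.treatment_temperatures
    }
    for sig in config.planted:
        gi = gene_index[sig.gene_id]
        for temp, fc in sig.log2fc_by_temperature.items():
            for tis in sig.target_tissues:
                out[(tis, temp)][gi] = fc
    return out


def _balance_planted_mass(
    base: np.ndarray,
    fc_by_temp: dict[float, np.ndarray],
) -> np.ndarray:
    """Rescale planted genes' baseline weights so expected library size is
    equal across temperatures.

    Up- and down-regulation are asymmetric in count space (a gene doubling
    adds more reads than a halving gene removes), so unadjusted planting
    shifts treatment library totals and library-size-only normalization
    would bias every null gene's fold change.  Two scalar rescalings fix
    this for the supported planting patterns: one equalizes the two halves
    of the inverse group across temperatures, one scales the consistently
    down-regulated group to absorb the up-regulated mass (least squares
    over temperatures when exact balance is impossible).
    """
    base = base.copy()
    temps = sorted(fc_by_temp)
    lfc = np.column_stack([fc_by_temp[t] for t in temps])  # genes x temps
    planted = np.any(lfc != 0, axis=1)
    if not planted.any():
        return base
    delta = np.exp2(lfc) - 1.0  # per-temp read-mass multiplier
    up = planted & np.all(lfc >= 0, axis=1)
    down = planted & np.all(lfc <= 0, axis=1)
    mixed = planted & ~up & ~down  # inverse-pattern genes

    def deficit(mask: np.ndarray) -> np.ndarray:
        return (base[mask, None] * delta[mask]).sum(axis=0)

    if mixed.any() and len(temps) >= 2:
        first_pos = mixed & (lfc[:, 0] > 0)
        first_neg = mixed & (lfc[:, 0] < 0)
        if first_pos.any() and first_neg.any():
            d_pos = deficit(first_pos)
            d_neg = deficit(first_neg)
            denom = d_neg[0] - d_neg[-1]
            if abs(denom) > 1e-12:
                gamma = (d_pos[-1] - d_pos[0]) / denom
                if gamma > 0:
                    base[first_neg] *= gamma
    if down.any():
        d_other = deficit(planted & ~down)
        d_down = deficit(down)
        denom = float(d_down @ d_down)
        if denom > 0:
            c = -float(d_other @ d_down) / denom
            if c > 0:
                base[down] *= c
    return base


def simulate_experiment(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame, SimTruth]:
    """Draw a full multi-tissue experiment with planted ground truth.

    Returns the count matrix (pooled samples), a sample sheet
    (``sample_id``, ``tissue``, ``temperature_c``, ``pool_size``), and the
    :class:`SimTruth` table.  Counts for each animal are
    NB(mean = lib_size x relative expression x 2^log2FC, dispersion phi),
    summed over ``pool_size`` animals per sample.
    """
    _validate_planted(config)
    # fixed-key child per tissue index: adding tissues never perturbs others
    children = [
        np.random.SeedSequence([config.seed, 1, ti]) for ti in range(config.n_tissues)
    ]
    lo, hi = config.baseline_logmean_range
    shared_log2mean = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0])
    ).uniform(lo, hi, size=config.n_genes)

    # tissue-exclusive genes, round-robin over tissues, chosen deterministically
    n_excl = int(round(config.frac_tissue_exclusive * config.n_genes))
    planted_ids = {s.gene_id for s in config.planted}
    exclusive_tissue = np.full(config.n_genes, -1)
    pool = [i for i, g in enumerate(config.gene_ids) if g not in planted_ids]
    for k, gi in enumerate(pool[-n_excl:] if n_excl else []):
        exclusive_tissue[gi] = k % config.n_tissues

    fc = _true_log2fc_matrix(config)
    phi = config.dispersion
    cols: list[np.ndarray] = []
    sample_rows: list[dict] = []
    for ti, tissue in enumerate(config.tissues):
        rng = np.random.default_rng(children[ti])
        offset = rng.normal(0.0, config.tissue_offset_sd, size=config.n_genes)
        base = np.exp2(shared_log2mean + offset)
        off_mask = (exclusive_tissue >= 0) & (exclusive_tissue != ti)
        base[off_mask] = 0.0
        if config.mass_balance and config.planted:
            base = _balance_planted_mass(
                base, {t: fc[(tissue, t)] for t in config.treatment_temperatures}
            )
        rel = base / base.sum()  # control-profile relative expression
        for temp in config.temperatures:
            lfc = (
                np.zeros(config.n_genes)
                if temp == CONTROL_TEMPERATURE
                else fc[(tissue, temp)]
            )
            expr = rel * np.exp2(lfc)
            for j in range(config.n_samples_per_group):
                sample = np.zeros(config.n_genes, dtype=np.int64)
                for _ in range(config.pool_size):
                    lib = rng.lognormal(
                        np.log(config.lib_size_mean)
                        - 0.5 * np.log1p(config.lib_size_cv**2),
                        np.sqrt(np.log1p(config.lib_size_cv**2)),
                    )
                    mu = lib * expr
                    if phi < 1e-12:
                        sample += rng.poisson(mu)
                    else:
                        r = 1.0 / phi
                        # NB(mean mu, var mu + phi mu^2); mu=0 -> count 0
                        nz = mu > 0
                        draw = np.zeros(config.n_genes, dtype=np.int64)
                        draw[nz] = rng.negative_binomial(r, r / (r + mu[nz]))
                        sample += draw
                sid = f"{tissue}_{format(temp, 'g')}C_r{j + 1}"
                sample_rows.append(
                    dict(
                        sample_id=sid,
                        tissue=tissue,
                        temperature_c=temp,
                        pool_size=config.pool_size,
                    )
                )
                cols.append(sample)

    counts = np.column_stack(cols)
    sheet = pd.DataFrame(sample_rows)
    cm = CountMatrix(config.gene_ids, list(sheet["sample_id"]), counts)

    role_by_gene = {g: "null" for g in config.gene_ids}
    for sig in config.planted:
        role_by_gene[sig.gene_id] = sig.role
    rows = []
    for tissue in config.tissues:
        for temp in config.temperatures:
            lfc = (
                np.zeros(config.n_genes)
                if temp == CONTROL_TEMPERATURE
                else fc[(tissue, temp)]
            )
            for gi, gene in enumerate(config.gene_ids):
                rows.append((gene, tissue, temp, lfc[gi], role_by_gene[gene]))
    truth = SimTruth(
        pd.DataFrame(
            rows, columns=["gene", "tissue", "temperature_c", "true_log2fc", "role"]
        )
    )
    return cm, sheet, truth


def simulate_null(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Null harness: identical expected expression at every temperature."""
    if config.planted:
        raise SimConfigError("simulate_null requires an empty planted list")
    cm, sheet, _ = simulate_experiment(config)
    return cm, sheet


# ---------------------------------------------------------------------------
# Standard planting and the committed toy fixture
# ---------------------------------------------------------------------------

def standard_planting(
    config: SimConfig,
    n_tissue_specific: int,
    n_shared: int,
    n_inverse: int,
    effect: float = 2.0,
    shared_breadth: int = 3,
) -> SimConfig:
    """Plant a deterministic panel of signals onto the first genes of ``config``.

    Tissue-specific genes alternate up/down and cycle over tissues; shared
    genes hit ``shared_breadth`` consecutive tissues with a common-direction
    effect; inverse genes (only if two treatment temperatures exist) get
    ``+effect`` at the coldest and ``-effect`` at the warmest treatment
    temperature in all tissues.
    """
    genes = config.gene_ids
    tissues = config.tissues
    treats = sorted(config.treatment_temperatures)
    if n_inverse and len(treats) < 2:
        raise SimConfigError("inverse signals need two treatment temperatures")
    signals: list[PlantedSignal] = []
    g = 0
    for i in range(n_tissue_specific):
        up = i % 2 == 0
        role = "tissue_specific_up" if up else "tissue_specific_down"
        fcmap = {t: (effect if up else -effect) for t in treats}
        signals.append(
            PlantedSignal(genes[g], role, (tissues[i % len(tissues)],), fcmap)
        )
        g += 1
    for i in range(n_shared):
        up = i % 2 == 0
        role = "shared_up" if up else "shared_down"
        start = i % len(tissues)
        target = tuple(
            tissues[(start + k) % len(tissues)]
            for k in range(min(shared_breadth, len(tissues)))
        )
        fcmap = {t: (effect if up else -effect) for t in treats}
        signals.append(PlantedSignal(genes[g], role, target, fcmap))
        g += 1
    for i in range(n_inverse):
        # alternate orientation so planted mass stays composition-balanced
        sgn = 1.0 if i % 2 == 0 else -1.0
        fcmap = {treats[0]: sgn * effect, treats[-1]: -sgn * effect}
        signals.append(PlantedSignal(genes[g], "inverse", tuple(tissues), fcmap))
        g += 1
    return replace(config, planted=tuple(signals))


TOY_SEED = 1729


def toy_config() -> SimConfig:
    cfg = SimConfig(
        n_tissues=3,
        n_genes=180,
        temperatures=(10.0, 22.0, 34.0),
        n_samples_per_group=3,
        pool_size=2,
        dispersion=0.1,
        baseline_logmean_range=(2.0, 7.0),
        tissue_offset_sd=1.0,
        frac_tissue_exclusive=0.1,
        lib_size_mean=200_000,
        seed=TOY_SEED,
        tissues=("iBAT", "ingSAT", "Liver"),
    )
    return standard_planting(cfg, n_tissue_specific=12, n_shared=6, n_inverse=1)


def make_toy_fixture() -> tuple[CountMatrix, pd.DataFrame, SimTruth]:
    """Seed-pinned 180-gene, 3-tissue, two-contrast fixture.

    Contains at least one gene of every planted role (exactly one inverse
    gene) and is bit-identical on every call; the copy committed under
    ``thermatlas/data/toy`` is regenerated by this function.
    """
    return simulate_experiment(toy_config())


def toy_fixture_dir():
    from pathlib import Path

    return Path(__file__).parent / "data" / "toy"


def write_toy_fixture(outdir=None) -> None:
    """(Re)write the committed copy of the toy fixture."""
    from .io_formats import write_counts, write_sample_sheet

    outdir = toy_fixture_dir() if outdir is None else outdir
    cm, sheet, truth = make_toy_fixture()
    write_counts(cm, outdir / "counts.tsv")
    write_sample_sheet(sheet, outdir / "samples.tsv")
    with open(outdir / "truth.csv", "w", newline="\n") as fh:
        truth.table.to_csv(fh, index=False, float_format="%g", lineterminator="\n")


def load_toy_fixture() -> tuple[CountMatrix, pd.DataFrame, SimTruth]:
    """Load the committed toy fixture (identical to ``make_toy_fixture()``)."""
    from .io_formats import read_counts, read_sample_sheet

    d = toy_fixture_dir()
    cm = read_counts(d / "counts.tsv")
    sheet = read_sample_sheet(d / "samples.tsv")
    truth = SimTruth(pd.read_csv(d / "truth.csv"))
    return cm, sheet, truth
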