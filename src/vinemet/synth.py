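"""Synthetic two-cultivar temperature-response cohorts.

No raw per-replicate data accompany the study this pipeline emulates, so every
downstream stage is exercised on generated cohorts with a known ground truth.
The generator plants the printed effect sizes: per-cultivar 35 vs 25 degC fold
changes and the Cabernet Sauvignon vs Shiraz offsets at 25 degC, over a panel
of 48 leaf metabolites annotated with six biochemical classes.

Model. Abundances are lognormal: on the log10 scale the mean of sample s,
metabolite m is

    log10 baseline_m + log10 tempFC_m[cultivar] * 1[35 degC]
                     + log10 cultFC25_m * 1[Cs]

and the noise is multivariate normal with marginal standard deviation
``noise_sd`` and a block-diagonal correlation structure: metabolites of the
same biochemical class share a planted correlation ``rho_block`` while
cross-class pairs are independent. Because the same noise law applies to every
group, ratios of arithmetic group means converge to the planted fold changes.

The 2x2 cell means are parametrized by three free factors per metabolite
(baseline = Sh@25, temp FC per cultivar, cultivar FC at 25 degC); the Cs/Sh
ratio at 35 degC is implied rather than independently planted, since four
printed values would overdetermine four cell means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AbundanceTable, BIOCHEMICAL_CLASSES, sorted_pair

logger = logging.getLogger(__name__)

CULTIVARS = ("Cs", "Sh")
TEMPERATURES = ("25", "35")
#: sampling days of the emulated design (days 2, 4, 6 of a 7-day exposure)
SAMPLING_DAYS = ("2", "4", "6")


@dataclass(frozen=True)
class EffectSpec:
    """Planted effects for one metabolite.

    ``temp_fold_change`` maps cultivar -> (mean at 35 degC) / (mean at 25 degC);
    ``cultivar_fold_change`` maps temperature -> Cs / Sh mean ratio as printed.
    Only the 25 degC cultivar ratio enters the generative model (see module
    docstring); the 35 degC entry is carried so the printed table reads back
    exactly.
    """

    metabolite: str
    baseline_mean: float = 100.0
    temp_fold_change: Mapping[str, float] = field(
        default_factory=lambda: {"Cs": 1.0, "Sh": 1.0}
    )
    cultivar_fold_change: Mapping[str, float] = field(
        default_factory=lambda: {"25": 1.0, "35": 1.0}
    )
    biochemical_class: str = "carboxylic acid"
    temp_significant: Mapping[str, bool] = field(
        default_factory=lambda: {"Cs": False, "Sh": False}
    )
    cultivar_significant: Mapping[str, bool] = field(
        default_factory=lambda: {"25": False, "35": False}
    )

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError(f"{self.metabolite}: baseline_mean must be > 0")
        for label, fc in (*self.temp_fold_change.items(),
                          *self.cultivar_fold_change.items()):
            if fc <= 0:
                raise ValueError(
                    f"{self.metabolite}: fold change for {label!r} must be > 0"
                )
        if self.biochemical_class not in BIOCHEMICAL_CLASSES:
            raise ValueError(
                f"{self.metabolite}: unknown class {self.biochemical_class!r}"
            )

    def cell_mean_log10(self, cultivar: str, temperature: str) -> float:
        """Planted log10 group mean of the underlying normal (noise excluded)."""
        mu = np.log10(self.baseline_mean)
        if temperature == "35":
            mu += np.log10(self.temp_fold_change[cultivar])
        if cultivar == "Cs":
            mu += np.log10(self.cultivar_fold_change["25"])
        return float(mu)


@dataclass(frozen=True)
class SimConfig:
    """Design of one synthetic cohort.

    ``n_replicates`` is the per cultivar x temperature cell size (default 12,
    the printed n); ``noise_sd`` is the marginal log10-scale standard
    deviation; ``block_correlation`` maps biochemical class -> within-class
    correlation in [0, 1). The seed is explicit so every run is reproducible.
    """

    effects: Sequence[EffectSpec]
    n_replicates: int = 12
    noise_sd: float = 0.10
    block_correlation: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.3 for c in BIOCHEMICAL_CLASSES}
    )
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_replicates < 3:
            raise ValueError("n_replicates must be >= 3 (rank tests undefined)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        names = [e.metabolite for e in self.effects]
        if len(set(names)) != len(names):
            raise ValueError("duplicate metabolites in effect panel")
        for cls, rho in self.block_correlation.items():
            if not (0.0 <= rho < 1.0):
                raise ValueError(
                    f"block correlation for class {cls!r} must lie in [0, 1); "
                    f"got {rho} (equicorrelation outside this range is not "
                    "positive semidefinite for all block sizes)"
                )

    def with_(self, **changes) -> "SimConfig":
        return replace(self, **changes)

    def annotation(self) -> dict[str, str]:
        return {e.metabolite: e.biochemical_class for e in self.effects}


def _fixture_frame(name: str) -> pd.DataFrame:
    ref = resources.files("vinemet.data").joinpath(name)
    if not ref.is_file():
        raise FileNotFoundError(f"packaged fixture {name!r} is missing")
    with resources.as_file(ref) as path:
        sep = "\t" if name.endswith(".tsv") else ","
        return pd.read_csv(path, sep=sep)


def load_class_annotation() -> dict[str, str]:
    """Packaged metabolite -> biochemical class map for the 48-metabolite panel."""
    frame = _fixture_frame("metabolite_classes.tsv")
    return dict(zip(frame["metabolite"], frame["class"]))


def load_temperature_fold_changes() -> pd.DataFrame:
    """The printed 35/25 degC fold-change table, cell for cell."""
    return _fixture_frame("temperature_fold_changes.csv")


def load_cultivar_fold_changes() -> pd.DataFrame:
    """The printed Cs/Sh fold-change table, cell for cell."""
    return _fixture_frame("cultivar_fold_changes.csv")


def load_fixture_effects(baseline_mean: float = 100.0) -> list[EffectSpec]:
    """One EffectSpec per panel metabolite, planted from the printed tables.

    Metabolites absent from a table default to the neutral fold change 1.0.
    The returned panel covers the full 48-metabolite class annotation, so the
    four metabolites named only in the network discussion (Thr, GABA,
    Pyroglutamate, Tartarate) carry neutral effects.
    """
    annotation = load_class_annotation()
    temp = load_temperature_fold_changes().set_index("metabolite")
    cult = load_cultivar_fold_changes().set_index("metabolite")
    for name in set(temp.index) | set(cult.index):
        if name not in annotation:
            raise ValueError(f"fixture metabolite {name!r} lacks a class")
    effects = []
    for name, cls in annotation.items():
        spec = EffectSpec(metabolite=name, baseline_mean=baseline_mean,
                          biochemical_class=cls)
        if name in temp.index:
            row = temp.loc[name]
            spec = replace(
                spec,
                temp_fold_change={"Cs": float(row["cs_35_25"]),
                                  "Sh": float(row["sh_35_25"])},
                temp_significant={"Cs": bool(row["cs_significant"]),
                                  "Sh": bool(row["sh_significant"])},
            )
        if name in cult.index:
            row = cult.loc[name]
            spec = replace(
                spec,
                cultivar_fold_change={"35": float(row["cs_sh_35"]),
                                      "25": float(row["cs_sh_25"])},
                cultivar_significant={"35": bool(row["sig_35"]),
                                      "25": bool(row["sig_25"])},
            )
        effects.append(spec)
    return effects


def default_config(seed: int = 1, **changes) -> SimConfig:
    """The stated-world default: printed effects, n = 12, noise_sd = 0.10."""
    return SimConfig(effects=load_fixture_effects(), seed=seed).with_(**changes)


def _noise_covariance(config: SimConfig) -> np.ndarray:
    """Block-diagonal correlation (by class) scaled to marginal sd noise_sd."""
    classes = [e.biochemical_class for e in config.effects]
    n = len(classes)
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if classes[i] == classes[j]:
                rho = config.block_correlation.get(classes[i], 0.0)
                corr[i, j] = corr[j, i] = rho
    # equicorrelated blocks with rho in [0,1) are PSD for every block size,
    # but guard anyway so a future structure change fails loudly
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin < -1e-10:
        offenders = sorted(
            {c for c, r in config.block_correlation.items() if r < 0 or r >= 1}
        )
        raise ValueError(
            f"requested block correlation matrix is not positive semidefinite "
            f"(min eigenvalue {eigmin:.3g}); offending classes: {offenders or classes}"
        )
    return corr * config.noise_sd**2


def generate_abundance_table(config: SimConfig) -> AbundanceTable:
    """Draw one cohort; identical config (seed included) => identical table.

    Sample layout: for each cultivar x temperature cell, ``n_replicates``
    samples with unique vine/replicate ids 1..n and days 2/4/6 assigned
    cyclically, mirroring repeated chamber experiments in which each vine
    contributes one averaged profile.
    """
    rng = np.random.default_rng(config.seed)
    cov = _noise_covariance(config)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    names = [e.metabolite for e in config.effects]
    meta_rows: list[dict[str, str]] = []
    blocks: list[np.ndarray] = []
    for cultivar in CULTIVARS:
        for temperature in TEMPERATURES:
            mu = np.array(
                [e.cell_mean_log10(cultivar, temperature) for e in config.effects]
            )
            z = rng.standard_normal((config.n_replicates, len(names)))
            log_abund = mu + z @ chol.T
            blocks.append(10.0 ** log_abund)
            for r in range(config.n_replicates):
                meta_rows.append(
                    {
                        "cultivar": cultivar,
                        "temperature": temperature,
                        "day": SAMPLING_DAYS[r % len(SAMPLING_DAYS)],
                        "replicate": str(r + 1),
                    }
                )
    samples = pd.DataFrame(meta_rows, columns=["cultivar", "temperature",
                                               "day", "replicate"])
    data = pd.DataFrame(np.vstack(blocks), columns=names)
    return AbundanceTable(samples, data)


def planted_truth(
    config: SimConfig, threshold: float = 0.5
) -> dict[tuple[str, str], bool]:
    """Ground-truth co-response flags for every unordered metabolite pair.

    A pair is flagged True when both members share a biochemical class whose
    planted block correlation is at or above ``threshold``; cross-class pairs
    (independent noise) and weakly correlated blocks are False. Used as the
    reference when scoring edge recovery of the correlation networks.
    """
    effects = list(config.effects)
    truth: dict[tuple[str, str], bool] = {}
    for i, a in enumerate(effects):
        for b in effects[i + 1:]:
            same = a.biochemical_class == b.biochemical_class
            rho = config.block_correlation.get(a.biochemical_class, 0.0)
            truth[sorted_pair(a.metabolite, b.metabolite)] = bool(
                same and rho >= threshold
            )
    return truth
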