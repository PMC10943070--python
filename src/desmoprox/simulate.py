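"""Synthetic BioID experiments with known ground truth.

The generator emulates a condition-resolved proximity-labeling study design:
four baits tagging three desmosomal proteins (Dsc2a at its C terminus, the
armadillo protein plakoglobin at both termini, plakophilin 2a at its
N terminus) plus a promiscuous-ligase-only control, each profiled in two
adhesion states (Ca2+-dependent vs hyper-adhesive desmosomes) in biological
triplicate — 30 samples with the defaults.

Intensities are simulated directly on the log2 scale. Each protein gets a
baseline abundance drawn from N(control_mean, control_sd) — the wide
between-protein spread of a proteome — and every sample measurement adds
independent N(0, replicate_sd) noise, the much smaller replicate-to-replicate
variation typical of label-free quantification. True interactors additionally
receive a per-condition log2 enrichment delta in the samples of their
assigned baits. Naturally biotinylated contaminants are high in every sample
including controls. Missingness combines a random background dropout rate
with intensity-thresholded left-censoring mimicking MS detection limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .quant_io import IntensityMatrix, SampleDesign, make_design

DEFAULT_BAITS = ("Dsc2a", "PG-N", "PG-C", "Pkp2a")
DEFAULT_CONDITIONS = ("ca_dependent", "hyper_adhesive")
CONTROL_LABEL = "BirA-myc"

#: log2 offset of contaminant rows over the background mean; large enough that
#: contaminants never hit the dropout threshold at default settings.
CONTAMINANT_OFFSET = 6.0

CATEGORIES = ("background", "constant", "calcium_dependent", "hyper_adhesive", "contaminant")


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of a simulated BioID experiment."""

    n_background_preys: int = 500
    n_constant: int = 30
    n_calcium_only: int = 30
    n_hyper_only: int = 20
    #: per-bait probability that a true prey attaches to that bait
    #: (independent Bernoulli draws; multi-bait preys model shared neighbors)
    bait_assignment_probs: dict = field(
        default_factory=lambda: {b: 0.4 for b in DEFAULT_BAITS}
    )
    n_replicates: int = 3
    baits: tuple = DEFAULT_BAITS
    conditions: tuple = DEFAULT_CONDITIONS
    control_mean: float = 20.0
    control_sd: float = 1.5
    #: within-protein replicate noise (log2); distinct from the between-protein
    #: baseline spread control_sd
    replicate_sd: float = 0.5
    enrichment_delta_mean: float = 3.0
    enrichment_delta_sd: float = 0.5
    missing_rate_background: float = 0.1
    #: log2 intensity below which a value is censored to missing; None disables
    dropout_threshold: float | None = 16.0
    n_contaminants: int = 10
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_background_preys",
            "n_constant",
            "n_calcium_only",
            "n_hyper_only",
            "n_contaminants",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        for name in ("control_sd", "replicate_sd", "enrichment_delta_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not 0.0 <= self.missing_rate_background <= 1.0:
            raise ConfigurationError("missing_rate_background must be in [0, 1]")
        for bait in self.baits:
            p = self.bait_assignment_probs.get(bait)
            if p is None or not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"bait_assignment_probs[{bait!r}] must be in [0, 1]"
                )
        if len(self.conditions) != 2:
            raise ConfigurationError("conditions must be a pair")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Per-prey truth labels: category, true bait set, per-condition delta.

    ``data`` columns: ``prey``, ``category``, ``baits`` ("/"-joined, empty for
    background and contaminants), one ``delta_<condition>`` column per
    condition.
    """

    data: pd.DataFrame
    conditions: tuple = DEFAULT_CONDITIONS

    def category_counts(self) -> dict:
        return self.data["category"].value_counts().to_dict()

    def bait_set(self, prey: str) -> frozenset:
        row = self.data.set_index("prey").loc[prey]
        return frozenset(b for b in str(row["baits"]).split("/") if b)

    def true_pairs(self) -> set:
        """All truly enriched (bait, condition, prey) triples."""
        pairs = set()
        for row in self.data.itertuples(index=False):
            baits = [b for b in str(row.baits).split("/") if b]
            for condition in self.conditions:
                if getattr(row, f"delta_{condition}") > 0:
                    for bait in baits:
                        pairs.add((bait, condition, row.prey))
        return pairs

    def to_csv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def _prey_names(config: SimulationConfig) -> tuple[list[str], list[str]]:
    names, categories = [], []
    for i in range(config.n_background_preys):
        names.append(f"BG{i + 1:04d}")
        categories.append("background")
    for i in range(config.n_constant):
        names.append(f"CONST{i + 1:03d}")
        categories.append("constant")
    for i in range(config.n_calcium_only):
        names.append(f"CAON{i + 1:03d}")
        categories.append("calcium_dependent")
    for i in range(config.n_hyper_only):
        names.append(f"HYPON{i + 1:03d}")
        categories.append("hyper_adhesive")
    named = ["PC", "MCCC1", "PCCA"]
    for i in range(config.n_contaminants):
        if i < len(named):
            names.append(named[i])
        elif i % 2 == 1:
            names.append(f"RPL{i + 1:02d}")
        else:
            names.append(f"RPS{i + 1:02d}")
        categories.append("contaminant")
    return names, categories


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[IntensityMatrix, SampleDesign, GroundTruth]:
    """Generate (log2 intensity matrix, sample design, ground truth).

    Deterministic: identical config (including seed) gives identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = make_design(
        config.baits, config.conditions, config.n_replicates, CONTROL_LABEL
    )
    samples = design.samples
    preys, categories = _prey_names(config)
    n_prey, n_samp = len(preys), len(samples)

    baseline = rng.normal(config.control_mean, config.control_sd, size=n_prey)
    is_contaminant = np.array([c == "contaminant" for c in categories])
    baseline[is_contaminant] += CONTAMINANT_OFFSET
    values = baseline[:, None] + rng.normal(
        0.0, config.replicate_sd, size=(n_prey, n_samp)
    )

    # true-prey bait assignment and per-condition enrichment deltas
    bait_list = list(config.baits)
    truth_rows = []
    sample_meta = design.data.set_index("sample")
    for i, (prey, category) in enumerate(zip(preys, categories)):
        baits: list[str] = []
        deltas = {c: 0.0 for c in config.conditions}
        if category in ("constant", "calcium_dependent", "hyper_adhesive"):
            picks = rng.random(len(bait_list))
            baits = [
                b
                for b, u in zip(bait_list, picks)
                if u < config.bait_assignment_probs[b]
            ]
            if not baits:
                baits = [bait_list[rng.integers(len(bait_list))]]
            active = (
                config.conditions
                if category == "constant"
                else (config.conditions[0],)
                if category == "calcium_dependent"
                else (config.conditions[1],)
            )
            for condition in active:
                deltas[condition] = rng.normal(
                    config.enrichment_delta_mean, config.enrichment_delta_sd
                )
            for j, sample in enumerate(samples):
                meta = sample_meta.loc[sample]
                if not meta["is_control"] and meta["bait"] in baits:
                    values[i, j] += deltas[meta["condition"]]
        truth_rows.append(
            {
                "prey": prey,
                "category": category,
                "baits": "/".join(baits),
                **{f"delta_{c}": deltas[c] for c in config.conditions},
            }
        )

    # missingness: random dropout on background prey cells, then left-censoring
    is_background = np.array([c == "background" for c in categories])
    if config.missing_rate_background > 0 and is_background.any():
        mask = rng.random((int(is_background.sum()), n_samp)) < config.missing_rate_background
        values[is_background] = np.where(mask, np.nan, values[is_background])
    if config.dropout_threshold is not None:
        with np.errstate(invalid="ignore"):
            values[values < config.dropout_threshold] = np.nan

    matrix = IntensityMatrix(
        pd.DataFrame(values, index=pd.Index(preys, name="prey"), columns=samples),
        provenance="raw",
    )
    truth = GroundTruth(pd.DataFrame(truth_rows), conditions=tuple(config.conditions))
    return matrix, design, truth


def write_experiment(outdir, matrix: IntensityMatrix, design: SampleDesign, truth: GroundTruth) -> dict:
    """Write the three artifact tables; returns their paths."""
    from pathlib import Path

    from .quant_io import write_protein_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": outdir / "intensities.tsv",
        "design": outdir / "design.csv",
        "truth": outdir / "truth.tsv",
    }
    write_protein_table(matrix, paths["intensities"])
    design.to_csv(paths["design"])
    truth.to_csv(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
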