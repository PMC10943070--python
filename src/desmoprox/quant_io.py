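"""Reading, contaminant filtering and normalization of protein intensity tables.

The exchange format is the MaxQuant ``proteinGroups``-style tab-delimited
table: a ``Protein IDs`` column followed by one linear-scale intensity column
per sample.  Internally all intensities live on the log2 scale with ``NaN``
marking missing values (a zero or blank intensity is "not detected", the
standard convention for label-free MS output).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, NormalizationError, SchemaError

logger = logging.getLogger(__name__)

PROTEIN_ID_COLUMN = "Protein IDs"

#: Naturally biotinylated mitochondrial carboxylases picked up by streptavidin
#: pull-downs regardless of bait: pyruvate carboxylase, methylcrotonoyl-CoA
#: carboxylase alpha, propionyl-CoA carboxylase alpha.
DEFAULT_CONTAMINANT_IDS = frozenset({"PC", "MCCC1", "PCCA"})

#: Ribosomal proteins can be biotinylated co-translationally; both large- and
#: small-subunit gene symbols are excluded by prefix.
DEFAULT_CONTAMINANT_PREFIXES = ("RPL", "RPS")


@dataclass(frozen=True)
class SampleDesign:
    """Sample annotation: which bait, condition and replicate each column is.

    ``data`` columns: ``sample``, ``bait``, ``condition``, ``replicate``,
    ``is_control``.  Control samples carry the control construct name in the
    ``bait`` column.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "bait", "condition", "replicate", "is_control"}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(f"design table missing columns: {sorted(missing)}")
        if self.data["sample"].duplicated().any():
            dupes = self.data.loc[self.data["sample"].duplicated(), "sample"].tolist()
            raise FormatError(f"duplicate sample IDs in design: {dupes}")

    @property
    def samples(self) -> list[str]:
        return self.data["sample"].tolist()

    @property
    def baits(self) -> list[str]:
        mask = ~self.data["is_control"]
        return list(dict.fromkeys(self.data.loc[mask, "bait"]))

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.data["condition"]))

    def bait_samples(self, bait: str, condition: str) -> list[str]:
        mask = (
            (self.data["bait"] == bait)
            & (self.data["condition"] == condition)
            & (~self.data["is_control"])
        )
        return self.data.loc[mask, "sample"].tolist()

    def control_samples(self, condition: str) -> list[str]:
        mask = (self.data["condition"] == condition) & (self.data["is_control"])
        return self.data.loc[mask, "sample"].tolist()

    @classmethod
    def from_csv(cls, path) -> "SampleDesign":
        df = pd.read_csv(path)
        df["is_control"] = df["is_control"].astype(bool)
        return cls(df)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class IntensityMatrix:
    """proteins x samples log2 intensities with explicit missingness.

    ``values``: DataFrame indexed by protein ID with one column per sample;
    NaN means not detected. ``provenance`` tracks the processing state
    (``raw`` | ``contaminant_filtered`` | ``median_centered``).
    """

    values: pd.DataFrame
    provenance: str = "raw"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate protein IDs: {dupes}")
        arr = self.values.to_numpy(dtype=float)
        present = ~np.isnan(arr)
        if not np.isfinite(arr[present]).all():
            raise FormatError("non-finite intensity values present")

    @property
    def proteins(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()


def read_protein_table(path, design: SampleDesign) -> IntensityMatrix:
    """Read a linear-scale protein table, log2-transform, order by design.

    Zeros and blanks become missing (NaN).  Column order follows the design;
    a design sample without a matching column raises :class:`SchemaError`.
    """
    df = pd.read_csv(path, sep="\t")
    if PROTEIN_ID_COLUMN not in df.columns:
        raise SchemaError(f"protein table lacks a {PROTEIN_ID_COLUMN!r} column")
    df = df.set_index(PROTEIN_ID_COLUMN)
    for sample in design.samples:
        if sample not in df.columns:
            raise SchemaError(f"no intensity column for design sample {sample!r}")
    values = df[design.samples].apply(pd.to_numeric, errors="coerce").astype(float)
    if (values.to_numpy() < 0).any():
        raise FormatError("negative linear-scale intensities")
    values = values.where(values > 0)  # 0 and blanks -> NaN
    return IntensityMatrix(np.log2(values), provenance="raw")


def write_protein_table(m: IntensityMatrix, path) -> None:
    """Write a matrix back to the linear-scale tab-delimited dialect (0 = missing)."""
    linear = np.exp2(m.values).fillna(0.0)
    linear.index.name = PROTEIN_ID_COLUMN
    linear.to_csv(path, sep="\t")


def filter_contaminants(
    m: IntensityMatrix,
    contaminant_ids=DEFAULT_CONTAMINANT_IDS,
    prefix_rules=DEFAULT_CONTAMINANT_PREFIXES,
) -> IntensityMatrix:
    """Remove labeling-artifact rows (named IDs or prefix matches).

    Surviving values are untouched; the removed IDs are logged.
    """
    ids = set(contaminant_ids or ())
    prefixes = tuple(prefix_rules or ())

    def is_contaminant(protein: str) -> bool:
        return protein in ids or (bool(prefixes) and protein.startswith(prefixes))

    keep = [p for p in m.proteins if not is_contaminant(p)]
    removed = [p for p in m.proteins if is_contaminant(p)]
    if removed:
        logger.info("filter_contaminants: removed %d rows: %s", len(removed), removed)
    return IntensityMatrix(m.values.loc[keep], provenance="contaminant_filtered")


def median_center(m: IntensityMatrix) -> IntensityMatrix:
    """Shift each sample so its median matches the grand median of sample medians.

    Centering on the grand median (rather than zero) preserves the intensity
    scale, keeping downstream fold changes interpretable.  The missingness
    pattern is unchanged.  Idempotent.
    """
    medians = m.values.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = medians.index[medians.isna()].tolist()
        raise NormalizationError(f"sample(s) with no present values: {bad}")
    grand = float(np.median(medians.to_numpy()))
    centered = m.values.add(grand - medians, axis=1)
    return IntensityMatrix(centered, provenance="median_centered")


def make_design(
    baits,
    conditions,
    n_replicates: int,
    control_label: str = "BirA-myc",
) -> SampleDesign:
    """Build the full-factorial bait x condition x replicate design plus
    per-condition control replicates; sample IDs follow
    ``<bait|control>_<condition>_rep<k>``."""
    rows = []
    for bait in baits:
        for condition in conditions:
            for rep in range(1, n_replicates + 1):
                rows.append(
                    dict(
                        sample=f"{bait}_{condition}_rep{rep}",
                        bait=bait,
                        condition=condition,
                        replicate=rep,
                        is_control=False,
                    )
                )
    for condition in conditions:
        for rep in range(1, n_replicates + 1):
            rows.append(
                dict(
                    sample=f"control_{condition}_rep{rep}",
                    bait=control_label,
                    condition=condition,
                    replicate=rep,
                    is_control=True,
                )
            )
    return SampleDesign(pd.DataFrame(rows))
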