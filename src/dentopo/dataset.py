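"""Specimen tables: delimited-text I/O, vocabulary checks, species means.

Analyses run on tables of specimen records (taxon, family, clade, tooth
locus, diet label, metric values).  Diet labels are validated against a
vocabulary config (a YAML file mirroring the seven-category scheme used in
comparative work) so alternative classification schemes can be swapped in
without code changes.  Classification runs on species means: per-species
arithmetic means of each metric, pooling the selected loci, with m2 and m3
of the same specimen treated as separate observations.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

METRIC_COLUMNS = (
    "rfi", "dne", "convex_dne", "ariadne", "ariadne_cv", "opcr", "lnoa", "tritahi",
)

REQUIRED_COLUMNS = ("specimen_id", "species", "clade", "locus", "diet")


class VocabularyError(ValueError):
    """A label falls outside the configured vocabulary."""


class ConsistencyError(ValueError):
    """Conflicting labels within a species, or duplicated specimen rows."""


@dataclass(frozen=True)
class DietVocabulary:
    diets: tuple
    loci: tuple
    clades: tuple

    @classmethod
    def default(cls) -> "DietVocabulary":
        text = (
            importlib.resources.files("dentopo.data")
            .joinpath("diet_vocabulary.yaml")
            .read_text()
        )
        return cls.from_yaml_text(text)

    @classmethod
    def from_yaml_text(cls, text: str) -> "DietVocabulary":
        cfg = yaml.safe_load(text)
        return cls(
            diets=tuple(cfg["diets"]),
            loci=tuple(cfg["loci"]),
            clades=tuple(cfg["clades"]),
        )


def load_table(
    path,
    column_map: dict | None = None,
    sep: str = ",",
    vocabulary: DietVocabulary | None = None,
) -> pd.DataFrame:
    """Read a delimited specimen table into a validated DataFrame.

    ``column_map`` maps file column names to canonical names (specimen_id,
    species, family, clade, locus, diet, and the metric columns).  Unknown
    diet labels raise :class:`VocabularyError` naming the row; duplicate
    (specimen_id, locus) pairs raise :class:`ConsistencyError`.  Missing
    metric cells stay missing (NaN), never zero.
    """
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    return validate_table(df, vocabulary=vocabulary)


def validate_table(
    df: pd.DataFrame, vocabulary: DietVocabulary | None = None
) -> pd.DataFrame:
    vocab = vocabulary or DietVocabulary.default()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"table is missing required columns: {missing}")
    for i, diet in df["diet"].items():
        if diet not in vocab.diets:
            raise VocabularyError(
                f"row {i}: unknown diet label {diet!r}; vocabulary: {vocab.diets}"
            )
    bad_locus = ~df["locus"].isin(vocab.loci)
    if bad_locus.any():
        i = df.index[bad_locus][0]
        raise VocabularyError(f"row {i}: unknown locus {df.loc[i, 'locus']!r}")
    dup = df.duplicated(subset=["specimen_id", "locus"], keep=False)
    if dup.any():
        key = df.loc[df.index[dup][0], ["specimen_id", "locus"]].tolist()
        raise ConsistencyError(f"duplicate specimen_id+locus: {key}")
    for col in METRIC_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def species_means(
    records: pd.DataFrame, loci: tuple = ("m2", "m3")
) -> pd.DataFrame:
    """Per-species arithmetic means over the selected loci.

    m2 and m3 observations of the same specimen are pooled as separate
    observations (so two-tooth specimens carry double weight, matching how
    combined-locus samples are built).  Species with conflicting diet or
    clade labels raise :class:`ConsistencyError`; species with no
    observation at the selected loci are absent from the output.
    """
    sub = records[records["locus"].isin(loci)]
    if len(sub) == 0:
        raise ValueError(f"no records at loci {loci}")
    for label in ("diet", "clade"):
        n_labels = sub.groupby("species")[label].nunique()
        bad = n_labels[n_labels > 1]
        if len(bad):
            sp = bad.index[0]
            vals = sorted(sub.loc[sub["species"] == sp, label].unique())
            raise ConsistencyError(f"species {sp!r} has conflicting {label}s: {vals}")
    metrics = [c for c in METRIC_COLUMNS if c in sub.columns]
    agg = {c: "mean" for c in metrics}
    agg.update({"diet": "first", "clade": "first"})
    out = sub.groupby("species", sort=True).agg(agg).reset_index()
    counts = sub.groupby("species", sort=True).size().values
    out["n_specimens"] = counts
    return out


def write_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)
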