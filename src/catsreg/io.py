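"""CSV/JSON readers and writers binding the pipeline together.

One unambiguous CSV dialect: comma-separated, UTF-8, mandatory header,
``.`` decimal separator.  All tables are joined on the ``species`` column;
the abundance file's row order is authoritative.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .diagnostics import ResidualSet
from .fitting import DesignSpec
from .offsets import MetaPrior, relative_abundances

__all__ = [
    "ValidationError",
    "read_community_tables",
    "read_hurdle_meta",
    "read_site_species_matrix",
    "write_abundance_csv",
    "write_traits_csv",
    "write_meta_csv",
    "write_partition_json",
    "write_residuals_csv",
]


class ValidationError(ValueError):
    """Aggregated input-validation failure; ``problems`` lists every issue."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid input tables:\n  - " + "\n  - ".join(self.problems))


def _read_csv(path, label, problems):
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface as validation problem
        problems.append(f"{label} table {path}: {exc}")
        return None
    if "species" not in df.columns:
        problems.append(f"{label} table {path}: missing 'species' column")
        return None
    if df["species"].duplicated().any():
        dups = df.loc[df["species"].duplicated(), "species"].tolist()
        problems.append(f"{label} table {path}: duplicate species ids {dups}")
    return df


def _numeric(df, cols, label, problems):
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), "species"].tolist()
            problems.append(f"{label} column '{c}': non-numeric values for species {bad}")
        df[c] = vals
    return df


def read_community_tables(abundance_csv, traits_csv=None, meta_csv=None):
    """Read and align abundance, trait and meta-community tables.

    Returns ``(y, species_ids, design, prior)``; ``design`` / ``prior`` are
    None when the corresponding file is not given.  Meta-community tables
    may cover a larger species pool (extras are dropped with a warning);
    missing species in any table are an error.
    """
    problems: list[str] = []
    ab = _read_csv(abundance_csv, "abundance", problems)
    if ab is not None:
        if "abundance" not in ab.columns:
            problems.append(f"abundance table {abundance_csv}: missing 'abundance' column")
        else:
            ab = _numeric(ab, ["abundance"], "abundance", problems)
    tr = _read_csv(traits_csv, "traits", problems) if traits_csv else None
    me = _read_csv(meta_csv, "meta", problems) if meta_csv else None
    if problems:
        raise ValidationError(problems)

    species = ab["species"].tolist()
    y = ab["abundance"].to_numpy(dtype=float)

    design = None
    if tr is not None:
        trait_cols = [c for c in tr.columns if c != "species"]
        if not trait_cols:
            problems.append(f"traits table {traits_csv}: no trait columns")
        tr = _numeric(tr, trait_cols, "traits", problems)
        missing = sorted(set(species) - set(tr["species"]))
        if missing:
            problems.append(f"traits table missing species {missing}")
        if not problems:
            tr = tr.set_index("species").loc[species]
            design = DesignSpec(
                tr[trait_cols].to_numpy(dtype=float),
                species_ids=tuple(species),
                trait_names=tuple(trait_cols),
            )

    prior = None
    if me is not None:
        if "mean_abundance" not in me.columns:
            problems.append(f"meta table {meta_csv}: missing 'mean_abundance' column")
        else:
            me = _numeric(me, ["mean_abundance"], "meta", problems)
            missing = sorted(set(species) - set(me["species"]))
            if missing:
                problems.append(f"meta table missing species {missing}")
            extra = sorted(set(me["species"]) - set(species))
            if extra and not problems:
                warnings.warn(
                    f"meta table covers {len(extra)} species absent from the "
                    f"abundance table; dropping them from the prior",
                    UserWarning,
                    stacklevel=2,
                )
            if not problems:
                me = me.set_index("species").loc[species]
                prior = relative_abundances(
                    me["mean_abundance"].to_numpy(dtype=float), species_ids=species
                )
    if problems:
        raise ValidationError(problems)
    return y, species, design, prior


def read_hurdle_meta(meta_csv, species):
    """Read hurdle-mode meta-community data.

    Expects columns ``species, presence_fraction, mean_when_present``;
    returns the two vectors aligned to the given species order.
    """
    problems: list[str] = []
    me = _read_csv(meta_csv, "meta", problems)
    if me is not None:
        for col in ("presence_fraction", "mean_when_present"):
            if col not in me.columns:
                problems.append(f"meta table {meta_csv}: missing '{col}' column")
        if not problems:
            me = _numeric(me, ["presence_fraction", "mean_when_present"], "meta", problems)
            missing = sorted(set(species) - set(me["species"]))
            if missing:
                problems.append(f"meta table missing species {missing}")
    if problems:
        raise ValidationError(problems)
    me = me.set_index("species").loc[list(species)]
    return (
        me["presence_fraction"].to_numpy(dtype=float),
        me["mean_when_present"].to_numpy(dtype=float),
    )


def read_site_species_matrix(path):
    """Read a site-by-species abundance matrix CSV (leading ``site`` column).

    Returns ``(site_ids, species_ids, matrix)`` with one row per site.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "site":
        raise ValidationError([f"matrix table {path}: first column must be 'site'"])
    sites = df["site"].tolist()
    species = [c for c in df.columns if c != "site"]
    mat = df[species].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValidationError([f"matrix table {path}: non-numeric abundance cells"])
    return sites, species, mat


def write_abundance_csv(path, species, y) -> None:
    pd.DataFrame({"species": species, "abundance": y}).to_csv(path, index=False)


def write_traits_csv(path, species, traits, names=None) -> None:
    traits = np.atleast_2d(np.asarray(traits, dtype=float))
    if traits.shape[0] == 1 and len(species) > 1:
        traits = traits.T
    names = names or [f"trait{i+1}" for i in range(traits.shape[1])]
    df = pd.DataFrame(traits, columns=list(names))
    df.insert(0, "species", species)
    df.to_csv(path, index=False)


def write_meta_csv(path, species, mean_abundance) -> None:
    pd.DataFrame({"species": species, "mean_abundance": mean_abundance}).to_csv(
        path, index=False
    )


def write_partition_json(path, part, **extra) -> None:
    payload = part.to_dict()
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_residuals_csv(path, species, resset: ResidualSet) -> None:
    pd.DataFrame(
        {"species": species, "fitted": resset.fitted, "residual": resset.residuals}
    ).to_csv(path, index=False)
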