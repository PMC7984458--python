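"""File formats and run reports.

All tables are TSV.  Conventions:

* ``map.tsv`` — columns ``marker``, ``cm`` (optionally ``lg``); positions in
  centimorgans, 0-based from the linkage-group start.
* ``parents.tsv`` — columns ``marker``, ``parent`` (P1/P2), ``h1..h4``: the
  phased allele labels on the four homologous chromosomes.  Allele labels
  are opaque strings.
* ``genotypes.tsv`` — long format, columns ``individual``, ``marker``,
  ``allele`` and either ``dosage`` (counts summing to 4 per
  individual/marker) or ``present`` (0/1); the value column name declares
  the scoring model.  Markers with no rows for an individual are missing.
* ``traits.tsv`` — columns ``individual``, ``value``.

Scan output is a LOD-profile TSV plus a JSON report validated by
:func:`validate_report`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["Dataset", "read_dataset", "write_dataset", "write_results", "validate_report"]

MAX_ALLELES = 8


@dataclass
class Dataset:
    """An autotetraploid mapping-population dataset for one linkage group."""

    cm_positions: np.ndarray
    markers: list
    parent1: list  # per marker: 4 phased allele labels
    parent2: list
    individuals: list
    observations: list  # per individual, per marker: dict / frozenset / None
    y: np.ndarray
    dosage_scoring: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cm_positions = np.asarray(self.cm_positions, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.validate()

    def validate(self) -> None:
        m = len(self.markers)
        if not (len(self.parent1) == len(self.parent2) == len(self.cm_positions) == m):
            raise ValueError("map and parental genotype tables are inconsistent")
        if len(self.individuals) != len(self.observations) or len(self.individuals) != len(self.y):
            raise ValueError("genotype and trait tables cover different individuals")
        for j, name in enumerate(self.markers):
            alleles = set(self.parent1[j]) | set(self.parent2[j])
            if len(alleles) > MAX_ALLELES:
                raise ValueError(f"marker {name}: more than {MAX_ALLELES} alleles segregate")
            for i, ind in enumerate(self.individuals):
                obs = self.observations[i][j]
                if obs is None:
                    continue
                if self.dosage_scoring:
                    if not isinstance(obs, Mapping):
                        raise ValueError(
                            f"marker {name}, individual {ind}: dosage observation expected"
                        )
                    if sum(obs.values()) != 4:
                        raise ValueError(
                            f"marker {name}, individual {ind}: dosages sum to "
                            f"{sum(obs.values())}, expected 4"
                        )


def read_dataset(
    map_path, parents_path, genotypes_path, traits_path, meta: dict | None = None
) -> Dataset:
    """Read and cross-validate the four tables of a mapping experiment."""
    mp = pd.read_csv(map_path, sep="\t")
    if not {"marker", "cm"} <= set(mp.columns):
        raise ValueError("map file needs 'marker' and 'cm' columns")
    mp = mp.sort_values("cm", kind="stable").reset_index(drop=True)
    markers = mp["marker"].astype(str).tolist()

    pr = pd.read_csv(parents_path, sep="\t", dtype=str)
    need = {"marker", "parent", "h1", "h2", "h3", "h4"}
    if not need <= set(pr.columns):
        raise ValueError(f"parents file needs columns {sorted(need)}")
    parent1, parent2 = [], []
    for name in markers:
        rows = pr[pr["marker"] == name]
        for plist, tag in ((parent1, "P1"), (parent2, "P2")):
            row = rows[rows["parent"] == tag]
            if len(row) != 1:
                raise ValueError(f"marker {name}: expected one {tag} row in parents file")
            plist.append(tuple(row.iloc[0][["h1", "h2", "h3", "h4"]]))

    gt = pd.read_csv(genotypes_path, sep="\t", dtype={"individual": str, "marker": str})
    if "dosage" in gt.columns:
        dosage_scoring, valcol = True, "dosage"
    elif "present" in gt.columns:
        dosage_scoring, valcol = False, "present"
    else:
        raise ValueError("genotypes file needs a 'dosage' or 'present' value column")

    tr = pd.read_csv(traits_path, sep="\t", dtype={"individual": str})
    if not {"individual", "value"} <= set(tr.columns):
        raise ValueError("traits file needs 'individual' and 'value' columns")
    individuals = tr["individual"].tolist()
    y = tr["value"].to_numpy(dtype=float)

    unknown = set(gt["individual"]) - set(individuals)
    if unknown:
        raise ValueError(f"genotyped individuals missing from traits table: {sorted(unknown)[:5]}")
    unknown_m = set(gt["marker"]) - set(markers)
    if unknown_m:
        raise ValueError(f"genotype rows for unmapped markers: {sorted(unknown_m)[:5]}")

    midx = {name: j for j, name in enumerate(markers)}
    iidx = {ind: i for i, ind in enumerate(individuals)}
    observations: list = [[None] * len(markers) for _ in individuals]
    for (ind, mk), grp in gt.groupby(["individual", "marker"], sort=False):
        i, j = iidx[ind], midx[mk]
        if dosage_scoring:
            observations[i][j] = {
                str(a): int(v) for a, v in zip(grp["allele"], grp[valcol]) if int(v) > 0
            }
        else:
            observations[i][j] = frozenset(
                str(a) for a, v in zip(grp["allele"], grp[valcol]) if int(v) > 0
            )

    return Dataset(
        cm_positions=mp["cm"].to_numpy(dtype=float),
        markers=markers,
        parent1=parent1,
        parent2=parent2,
        individuals=individuals,
        observations=observations,
        y=y,
        dosage_scoring=dosage_scoring,
        meta=dict(meta or {}),
    )


def write_dataset(ds: Dataset, outdir) -> "dict[str, Path]":
    """Write the four tables; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    mp = pd.DataFrame({"marker": ds.markers, "cm": ds.cm_positions})
    paths["map"] = outdir / "map.tsv"
    mp.to_csv(paths["map"], sep="\t", index=False)

    rows = []
    for j, name in enumerate(ds.markers):
        rows.append([name, "P1", *ds.parent1[j]])
        rows.append([name, "P2", *ds.parent2[j]])
    pd.DataFrame(rows, columns=["marker", "parent", "h1", "h2", "h3", "h4"]).to_csv(
        outdir / "parents.tsv", sep="\t", index=False
    )
    paths["parents"] = outdir / "parents.tsv"

    valcol = "dosage" if ds.dosage_scoring else "present"
    grows = []
    for i, ind in enumerate(ds.individuals):
        for j, name in enumerate(ds.markers):
            obs = ds.observations[i][j]
            if obs is None:
                continue
            if ds.dosage_scoring:
                for a in sorted(obs):
                    grows.append([ind, name, a, int(obs[a])])
            else:
                for a in sorted(obs):
                    grows.append([ind, name, a, 1])
    pd.DataFrame(grows, columns=["individual", "marker", "allele", valcol]).to_csv(
        outdir / "genotypes.tsv", sep="\t", index=False
    )
    paths["genotypes"] = outdir / "genotypes.tsv"

    pd.DataFrame({"individual": ds.individuals, "value": ds.y}).to_csv(
        outdir / "traits.tsv", sep="\t", index=False
    )
    paths["traits"] = outdir / "traits.tsv"
    return paths


# ---------------------------------------------------------------------------
# scan output

REPORT_SCHEMA = {
    "version": str,
    "seed": (int, type(None)),
    "n_used": int,
    "dropped": list,
    "best_configuration": str,
    "peak_cm": float,
    "peak_lod": float,
    "bic": float,
    "effects": dict,
    "vg_percent": float,
    "rho_additive_percent": float,
    "threshold": (float, type(None)),
    "n_perm": int,
    "settings": dict,
}


def validate_report(report: dict) -> None:
    """Structural validation of a scan report (raises on violation)."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} has type {type(report[key]).__name__}")
    for k, v in report.items():
        _assert_finite(k, v)


def _assert_finite(key, value) -> None:
    if isinstance(value, float) and not math.isfinite(value):
        raise ValueError(f"non-finite value in report at {key!r}")
    if isinstance(value, dict):
        for k, v in value.items():
            _assert_finite(f"{key}.{k}", v)
    if isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            _assert_finite(f"{key}[{i}]", v)


def scan_report(result, n_perm: int = 0) -> dict:
    from . import __version__

    return {
        "version": __version__,
        "seed": result.seed,
        "n_used": int(result.n_used),
        "dropped": list(result.dropped),
        "best_configuration": result.best_config.label,
        "peak_cm": float(result.peak_cm),
        "peak_lod": float(result.peak_lod),
        "bic": float(result.bic),
        "effects": result.effects.as_dict(),
        "vg_percent": float(result.vg_percent),
        "rho_additive_percent": float(result.rho_additive),
        "threshold": None if result.threshold is None else float(result.threshold),
        "n_perm": int(n_perm),
        "settings": result.settings,
    }


def write_results(result, outdir, n_perm: int = 0) -> "dict[str, Path]":
    """Write the LOD profile TSV and the JSON run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prof = pd.DataFrame(
        {
            "cm": result.positions_cm,
            "interval": result.intervals,
            "r1": result.r1,
            "lod": result.lod,
            "bic_best_config": result.bic_by_config[result.best_config_index],
        }
    )
    paths = {"profile": outdir / "lod_profile.tsv", "report": outdir / "report.json"}
    prof.to_csv(paths["profile"], sep="\t", index=False, float_format="%.6g")
    report = scan_report(result, n_perm=n_perm)
    validate_report(report)
    with open(paths["report"], "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
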