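"""Reading and writing the delimited formats of the pipeline.

Time series travel as comma-separated tables with columns
``replicate_id, time_h, atom13C_pct, nh4_n_mg_l, no2_n_mg_l`` (isotope and
chemistry cells may be empty on a given row — the two series need not share a
grid), with flask metadata in a small YAML config.  Atom percentages are
converted to fractions on read and back to percent on write.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .errors import ConfigError
from .isotope import (
    DEFAULT_CARBON_FRACTION,
    ChemTimePoint,
    IncubationReplicate,
    IsotopeTimePoint,
)
from .regression import YieldEstimate
from .simulate import ExperimentBundle

TIMESERIES_COLUMNS = [
    "replicate_id", "time_h", "atom13C_pct", "nh4_n_mg_l", "no2_n_mg_l",
]

YIELD_COLUMNS = [
    "guild", "substrate", "temperature_c", "y_max_gvss_per_gn", "sd", "n",
    "r_squared", "scenario",
]


def read_metadata(path: str | Path) -> dict:
    """Flask metadata: vss0, substrate, temperature_c, a13c_medium_pct, ..."""
    with open(path) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict):
        raise ConfigError(f"metadata file {path} must be a key-value mapping")
    for key in ("vss0", "substrate"):
        if key not in meta:
            raise ConfigError(f"metadata missing required key {key!r}")
    return meta


def read_timeseries(
    data_path: str | Path, metadata: dict | str | Path
) -> list[IncubationReplicate]:
    """Load one incubation experiment (one or more flasks) from disk."""
    if not isinstance(metadata, dict):
        metadata = read_metadata(metadata)
    df = pd.read_csv(data_path)
    missing = set(TIMESERIES_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"time-series table missing columns {sorted(missing)}")

    a_medium = metadata.get("a13c_medium_pct", 99.0) / 100.0
    replicates = []
    for rep_id, group in df.groupby("replicate_id", sort=False):
        group = group.sort_values("time_h")
        iso_rows = group.dropna(subset=["atom13C_pct"])
        iso = [
            IsotopeTimePoint(float(r.time_h), float(r.atom13C_pct) / 100.0)
            for r in iso_rows.itertuples()
        ]
        chem_rows = group[
            group["nh4_n_mg_l"].notna() | group["no2_n_mg_l"].notna()
        ]
        chem = [
            ChemTimePoint(
                float(r.time_h),
                nh4_n=0.0 if pd.isna(r.nh4_n_mg_l) else float(r.nh4_n_mg_l),
                no2_n=0.0 if pd.isna(r.no2_n_mg_l) else float(r.no2_n_mg_l),
            )
            for r in chem_rows.itertuples()
        ]
        vss0 = metadata["vss0"]
        if isinstance(vss0, dict):  # per-flask measured values
            vss0 = vss0[str(rep_id)]
        replicates.append(
            IncubationReplicate(
                isotope_series=iso,
                chem_series=chem,
                vss0=float(vss0),
                substrate=metadata["substrate"],
                temperature=float(metadata.get("temperature_c", 20.0)),
                a13C_medium=a_medium,
                carbon_fraction=float(
                    metadata.get("carbon_fraction", DEFAULT_CARBON_FRACTION)
                ),
                replicate_id=str(rep_id),
            )
        )
    if not replicates:
        raise ConfigError(f"no replicates found in {data_path}")
    return replicates


def timeseries_frame(replicates: Iterable[IncubationReplicate]) -> pd.DataFrame:
    """Replicates back into the standard delimited layout (percent scale)."""
    rows = []
    for rep in replicates:
        chem_by_time = {p.time: p for p in rep.chem_series}
        iso_times = {p.time for p in rep.isotope_series}
        for p in rep.isotope_series:
            chem = chem_by_time.get(p.time)
            rows.append(
                {
                    "replicate_id": rep.replicate_id,
                    "time_h": p.time,
                    "atom13C_pct": p.a13C * 100.0,
                    "nh4_n_mg_l": chem.nh4_n if chem else None,
                    "no2_n_mg_l": chem.no2_n if chem else None,
                }
            )
        for p in rep.chem_series:
            if p.time not in iso_times:
                rows.append(
                    {
                        "replicate_id": rep.replicate_id,
                        "time_h": p.time,
                        "atom13C_pct": None,
                        "nh4_n_mg_l": p.nh4_n,
                        "no2_n_mg_l": p.no2_n,
                    }
                )
    return pd.DataFrame(rows, columns=TIMESERIES_COLUMNS)


def write_timeseries(
    replicates: Iterable[IncubationReplicate], path: str | Path
) -> None:
    timeseries_frame(replicates).to_csv(path, index=False)


def yield_table(estimates: Sequence[YieldEstimate]) -> pd.DataFrame:
    """Yield estimates as the standard results table."""
    return pd.DataFrame(
        [
            {
                "guild": e.guild,
                "substrate": e.substrate,
                "temperature_c": e.temperature,
                "y_max_gvss_per_gn": e.y_max,
                "sd": e.sd,
                "n": e.n_replicates,
                "r_squared": e.r_squared,
                "scenario": e.scenario,
            }
            for e in estimates
        ],
        columns=YIELD_COLUMNS,
    )


def write_bundle(bundle: ExperimentBundle, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated experiment bundle: data CSVs, metadata, truth file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for substrate, sims in (
        ("ammonium", bundle.ammonium),
        ("nitrite", bundle.nitrite),
    ):
        reps = [s.replicate for s in sims]
        data_path = outdir / f"{bundle.preset}_{substrate}.csv"
        write_timeseries(reps, data_path)
        meta = {
            "vss0": {r.replicate_id: float(r.vss0) for r in reps},
            "substrate": substrate,
            "temperature_c": float(bundle.temperature),
            "a13c_medium_pct": float(reps[0].a13C_medium * 100.0),
            "carbon_fraction": float(reps[0].carbon_fraction),
        }
        meta_path = outdir / f"{bundle.preset}_{substrate}_meta.yaml"
        with open(meta_path, "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)
        paths[f"{substrate}_data"] = data_path
        paths[f"{substrate}_meta"] = meta_path
    truth = {
        "preset": bundle.preset,
        "temperature_c": float(bundle.temperature),
        "true_total_yield": float(bundle.true_total_yield),
        "true_nob_yield": float(bundle.true_nob_yield),
    }
    truth_path = outdir / f"{bundle.preset}_truth.yaml"
    with open(truth_path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=False)
    paths["truth"] = truth_path
    return paths
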