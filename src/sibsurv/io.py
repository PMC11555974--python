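"""File formats, packaged worked examples, and fixture generation.

The canonical interchange format for full sibling histories is a delimited
text table with the columns

    resp_id, resp_birth_cmc, cluster, stratum, weight, interview_cmc,
    sib_sex ('f'/'m'), sib_alive (0/1), sib_birth_cmc, sib_death_cmc

with all dates as century-month codes (months since January 1900) and
``sib_death_cmc`` empty for siblings alive at the interview.  A ``dhs``
dialect maps the DHS sibling-recode variable names (mm1, mm2, mm4, mm8,
v005, v008, v021, v023) onto this schema.

Fixture generation reuses the microsimulator at reduced scale: a named
scenario (or an explicit :class:`~sibsurv.microsim.SimConfig`) is simulated,
its full sibling histories and summary tabulation are written as CSV, and
the generating life table's true 5pn / 35q15 are stored alongside so tests
can assert against the ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from sibsurv import __version__ as _version
from sibsurv.coefficients import SummaryTabulation, tabulate_summary
from sibsurv.direct import validate_ssh
from sibsurv.microsim import Population, PopulationExtinct, SimConfig, extract_ssh, run_simulation
from sibsurv.schedules import _load_packaged_csv, chain_35q15

__all__ = [
    "CANONICAL_COLUMNS",
    "read_ssh_table",
    "write_ssh_table",
    "read_summary_table",
    "generate_fixture",
    "hot_deck_impute",
    "FIXTURE_SCENARIOS",
    "load_worked_example",
    "write_manifest",
]

CANONICAL_COLUMNS = [
    "resp_id", "resp_birth_cmc", "cluster", "stratum", "weight",
    "interview_cmc", "sib_sex", "sib_alive", "sib_birth_cmc", "sib_death_cmc",
]

_DHS_MAP = {
    "caseid": "resp_id",
    "v011": "resp_birth_cmc",
    "v021": "cluster",
    "v023": "stratum",
    "v005": "weight",
    "v008": "interview_cmc",
    "mm1": "sib_sex",
    "mm2": "sib_alive",
    "mm4": "sib_birth_cmc",
    "mm8": "sib_death_cmc",
}


def read_ssh_table(path, dialect: str = "canonical") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a full-SSH table; returns (valid rows, rejects report).

    Row-level validation failures (death before birth, missing status, ...)
    are collected into the rejects frame with a ``reject_reason`` column,
    never silently dropped.  Missing mandatory columns raise by name.
    """
    df = pd.read_csv(path, comment="#")
    if dialect == "dhs":
        df = df.rename(columns={k: v for k, v in _DHS_MAP.items() if k in df.columns})
        if "sib_sex" in df and df["sib_sex"].dtype.kind in "if":
            df["sib_sex"] = np.where(df["sib_sex"] == 2, "f", "m")
        if "sib_alive" in df and df["sib_alive"].dtype.kind in "if":
            df["sib_alive"] = df["sib_alive"] == 1
        if "weight" in df:
            df["weight"] = df["weight"] / 1e6  # DHS weights are scaled by 1e6
    elif dialect != "canonical":
        raise ValueError(f"unknown dialect {dialect!r}")
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns and c != "resp_birth_cmc"]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")
    return validate_ssh(df)


def write_ssh_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in CANONICAL_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


def read_summary_table(path) -> SummaryTabulation:
    """Read a summary tabulation from CSV.

    Accepts either raw pooled counts (columns n, age_group, sib_sex,
    reached15, died, died_last5) or published proportions (columns
    age_group, s_t, s_tm5), as printed in worked examples.
    """
    df = pd.read_csv(path, comment="#")
    if {"s_t", "s_tm5"}.issubset(df.columns) and "reached15" not in df.columns:
        return SummaryTabulation.from_proportions(
            df["age_group"], df["s_t"], df["s_tm5"],
            sib_sex=df["sib_sex"].iloc[0] if "sib_sex" in df else "f",
        )
    from sibsurv.coefficients import _derive_proportions

    return SummaryTabulation(table=_derive_proportions(df))


#: Named reduced-scale scenarios for fixture generation.
FIXTURE_SCENARIOS = {
    "low_mortality": SimConfig(alpha_m=-1.0, beta_m=0.7, alpha_f=0.1, beta_f=1.4,
                               r=0.01, target_final_size=4000),
    "high_mortality": SimConfig(alpha_m=0.2, beta_m=1.1, alpha_f=-0.2, beta_f=1.15,
                                r=0.01, target_final_size=4000),
    "fast_growth": SimConfig(alpha_m=-0.6, beta_m=1.1, alpha_f=0.1, beta_f=1.0,
                             r=0.03, target_final_size=4000),
    "slow_growth": SimConfig(alpha_m=-0.6, beta_m=1.1, alpha_f=-0.2, beta_f=1.8,
                             r=0.01, target_final_size=4000),
}


def generate_fixture(scenario, seed: int, out_dir, n_clusters: int = 20,
                     max_retries: int = 5) -> dict:
    """Simulate a small population and write its fixtures.

    Writes ``<scenario>_ssh.csv`` (full sibling histories in the canonical
    schema), ``<scenario>_summary.csv`` (summary tabulation) and
    ``<scenario>_truth.json`` (the generating life table's 5pn and 35q15 and
    the config used).  On extinction the run is reseeded (logged in the truth
    record) up to ``max_retries`` times.  Returns the truth record.
    """
    if isinstance(scenario, str):
        name, base = scenario, FIXTURE_SCENARIOS[scenario]
    else:
        name, base = "custom", scenario
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reseeds = []
    pop = None
    for attempt in range(max_retries):
        cfg = SimConfig(**{**asdict(base), "seed": seed + attempt})
        try:
            pop = run_simulation(cfg)
            break
        except PopulationExtinct:
            reseeds.append(seed + attempt)
    if pop is None:
        raise PopulationExtinct(f"scenario {name}: extinct in {max_retries} attempts")
    rng = np.random.default_rng(cfg.seed)
    ssh = extract_ssh(pop)
    full = ssh.to_full_ssh(rng=rng, n_clusters=n_clusters)
    write_ssh_table(full, out_dir / f"{name}_ssh.csv")
    tab = tabulate_summary(full)
    tab.table.to_csv(out_dir / f"{name}_summary.csv", index=False)

    lt = cfg.life_table()
    five_pn = {n: lt.five_pn(n) for n in range(15, 50, 5)}
    truth = {
        "scenario": name,
        "config": asdict(cfg),
        "reseeded_from": reseeds,
        "five_pn": {str(k): v for k, v in five_pn.items()},
        "q35_15": chain_35q15(list(five_pn.values())),
        "e0": lt.e0,
        "final_size": pop.final_size,
    }
    (out_dir / f"{name}_truth.json").write_text(json.dumps(truth, indent=2))
    return truth


def hot_deck_impute(df: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Fill missing sibling dates from random same-status donor rows.

    A deliberately simple hot deck for *fixtures only* (real DHS files come
    with dates already imputed, and the estimators consume those as-is; no
    reader applies this automatically).  Missing birth CMCs are drawn from
    donors of the same survival status; missing death CMCs of dead siblings
    are drawn from dead donors and shifted to the recipient's birth month
    when that would precede it.
    """
    rng = np.random.default_rng(seed)
    out = df.copy()
    dead = ~out["sib_alive"].astype(bool)
    for col, pool_mask in (("sib_birth_cmc", slice(None)), ("sib_death_cmc", dead)):
        need = out[col].isna() & (dead if col == "sib_death_cmc" else True)
        donors = out.loc[pool_mask, col].dropna().to_numpy()
        if need.any():
            if len(donors) == 0:
                raise ValueError(f"no donor rows to impute {col}")
            out.loc[need, col] = rng.choice(donors, size=int(need.sum()))
    late = out["sib_death_cmc"].notna() & (out["sib_death_cmc"] < out["sib_birth_cmc"])
    out.loc[late, "sib_death_cmc"] = out.loc[late, "sib_birth_cmc"]
    return out


def load_worked_example(name: str) -> pd.DataFrame:
    """Packaged printed-table inputs: 'table1', 'table2', 'table5', 'table6'."""
    files = {
        "table1": "zw2015_table1_direct.csv",
        "table2": "zw2015_table2_lifetime.csv",
        "table5": "zw2015_table5_recent.csv",
        "table6": "zw_table6_two_survey.csv",
    }
    if name not in files:
        raise KeyError(f"unknown worked example {name!r}; options {sorted(files)}")
    return _load_packaged_csv(files[name])


def write_manifest(path, config: dict) -> None:
    """Run manifest: exact configuration, seed and package version."""
    manifest = {"package": "sibsurv", "version": _version, **config}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
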