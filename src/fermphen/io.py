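"""Readers, writers and the end-to-end pipeline.

All interchange is long/tidy CSV (UTF-8, ``.`` decimal separator, mandatory
header row).  Weighing logs are long tables with one row per balance reading
(``vial_id, strain, must, shaking, volume_mL, replicate, time_h, weight_g``);
kinetic parameters, ANOVA decompositions and phenomics outputs are tidy
one-row-per-entity tables.  Times are hours from inoculation; volumes are mL
in files and converted internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gxe import Lm1Model, cv_table
from .kinetics import Co2CurveModel, FermentationRecord
from .must import MustComposition, read_must_table
from .phenomics import (
    normalize_by_must,
    pca,
    rank_clustermap,
    robustness_analysis,
    strain_dispersion,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_weighing_log",
    "write_weighing_log",
    "write_kinetic_params",
    "extract_all_kinetics",
    "import_spreadsheet",
    "ExperimentConfig",
    "run_pipeline",
]

WEIGHING_COLUMNS = [
    "vial_id", "strain", "must", "shaking", "volume_mL", "replicate", "time_h", "weight_g",
]

KINETIC_TRAITS = ["lp", "t35", "t50", "t80", "v50_80", "co2max"]


def read_weighing_log(path: str | Path, sep: str | None = None) -> list[FermentationRecord]:
    """Read a long-format weighing log into one record per vial.

    Rows are sorted by time within each vial; duplicated (vial, time) pairs
    and design labels that vary within a vial are errors.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(WEIGHING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"weighing log {path} lacks columns: {sorted(missing)}")

    records = []
    for vial, grp in df.groupby("vial_id", sort=True):
        grp = grp.sort_values("time_h")
        if grp["time_h"].duplicated().any():
            t = grp.loc[grp["time_h"].duplicated(), "time_h"].iloc[0]
            raise ValueError(f"vial {vial!r}: duplicated weighing time {t} h")
        labels = grp[["strain", "must", "shaking", "volume_mL", "replicate"]].drop_duplicates()
        if len(labels) > 1:
            raise ValueError(f"vial {vial!r}: inconsistent design labels across rows")
        lab = labels.iloc[0]
        records.append(
            FermentationRecord(
                vial_id=str(vial),
                strain=str(lab["strain"]),
                must_code=str(lab["must"]),
                shaking=bool(lab["shaking"]),
                volume=float(lab["volume_mL"]),
                replicate=int(lab["replicate"]),
                times=grp["time_h"].to_numpy(dtype=float),
                weights=grp["weight_g"].to_numpy(dtype=float),
            )
        )
    return records


def write_weighing_log(records: list[FermentationRecord], path: str | Path) -> None:
    """Write records to the long CSV schema :func:`read_weighing_log` reads."""
    frames = []
    for r in records:
        frames.append(pd.DataFrame({
            "vial_id": r.vial_id, "strain": r.strain, "must": r.must_code,
            "shaking": r.shaking, "volume_mL": r.volume, "replicate": r.replicate,
            "time_h": r.times, "weight_g": r.weights,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def extract_all_kinetics(
    records: list[FermentationRecord],
    musts: list[MustComposition],
    span: float = 0.45,
    grid_step: float = 0.1,
) -> pd.DataFrame:
    """Fit every vial's curve model and tabulate the six kinetic traits."""
    by_code = {m.code: m for m in musts}
    rows = []
    for r in records:
        if r.must_code not in by_code:
            raise ValueError(f"vial {r.vial_id!r}: unknown must {r.must_code!r}")
        res = Co2CurveModel(r, span=span, grid_step=grid_step).fit(
            tco2max=by_code[r.must_code].tco2max
        )
        rows.append({
            "vial_id": r.vial_id, "strain": r.strain, "must": r.must_code,
            "shaking": r.shaking, "replicate": r.replicate,
            **res.params.to_dict(),
        })
    return pd.DataFrame(rows)


def write_kinetic_params(table: pd.DataFrame, path: str | Path) -> None:
    """One tidy row per vial: six kinetic traits plus quality flags."""
    table.to_csv(path, index=False)


def import_spreadsheet(path: str | Path, out_csv: str | Path, sheet: int | str = 0) -> pd.DataFrame:
    """Convert one sheet of a supplementary-style spreadsheet to tidy CSV."""
    df = pd.read_excel(path, sheet_name=sheet)
    df.to_csv(out_csv, index=False)
    return df


@dataclass
class ExperimentConfig:
    """Configuration of a full pipeline run (see ``run_pipeline``)."""

    weighing_log: str | None = None
    metabolite_table: str | None = None
    must_table: str | None = None
    output_dir: str = "fermphen_out"
    # kinetics
    span: float = 0.45
    grid_step: float = 0.1
    # gxe
    n_perm: int = 5000
    seed: int | None = None
    alpha: float = 0.05
    run_gxe: bool = True
    # phenomics
    run_phenomics: bool = True
    trait_classes: dict = field(default_factory=dict)
    quartile_fraction: float = 0.25

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("weighing_log", "metabolite_table", "must_table"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.run_gxe and self.n_perm > 0 and self.seed is None:
            raise ValueError("a seed is required when permutation tests are configured")


def run_pipeline(config: ExperimentConfig) -> Path:
    """Run kinetics -> trait assembly -> G x E / phenomics on configured inputs.

    Writes tidy CSV artifacts plus ``run.log`` into ``config.output_dir`` and
    returns that directory.  Deterministic stages are bit-reproducible for a
    fixed config; every stochastic stage's seed is recorded in the log.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("fermphen")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        if config.must_table is None:
            raise ValueError("config.must_table is required")
        musts = read_must_table(config.must_table)
        logger.info("stage musts: read %d must compositions", len(musts))

        trait_frames = []
        if config.weighing_log is not None:
            records = read_weighing_log(config.weighing_log)
            logger.info("stage kinetics: %d vials, span=%g, grid_step=%g",
                        len(records), config.span, config.grid_step)
            kin = extract_all_kinetics(records, musts, config.span, config.grid_step)
            write_kinetic_params(kin, out / "kinetic_params.csv")
            trait_frames.append(kin.drop(columns=["tco2max", "flags"]))

        if config.metabolite_table is not None:
            met = pd.read_csv(config.metabolite_table)
            logger.info("stage metabolites: %d rows", len(met))
            trait_frames.append(met)

        if not trait_frames:
            raise ValueError("config must provide a weighing log and/or a metabolite table")
        traits = trait_frames[0]
        for extra in trait_frames[1:]:
            traits = traits.merge(
                extra, on=[c for c in ("vial_id", "strain", "must", "shaking", "replicate")
                           if c in traits.columns and c in extra.columns],
                how="outer",
            )
        traits.to_csv(out / "trait_table.csv", index=False)
        design_cols = {"vial_id", "strain", "must", "shaking", "replicate"}
        trait_names = [c for c in traits.columns if c not in design_cols]

        if config.run_gxe:
            logger.info("stage gxe: n_perm=%d seed=%s", config.n_perm, config.seed)
            frames = []
            for t in trait_names:
                sub = traits.dropna(subset=[t])
                res = Lm1Model(sub, response=t).fit(n_perm=config.n_perm, seed=config.seed)
                frames.append(res.to_frame())
            pd.concat(frames, ignore_index=True).to_csv(out / "lm1_decomposition.csv", index=False)

            traits_cv = traits.assign(
                condition=traits["must"].astype(str) + "|" + traits["shaking"].astype(str)
            )
            cv = cv_table(traits_cv, trait_names)
            cv.per_cell.to_csv(out / "cv_per_cell.csv", index=False)
            cv.per_condition.to_csv(out / "cv_per_condition.csv")

        if config.run_phenomics:
            logger.info("stage phenomics: traits=%s", trait_names)
            means = traits.groupby(["strain", "must"], as_index=False)[trait_names].mean()
            norm = normalize_by_must(means, trait_names)
            norm.to_csv(out / "normalized_means.csv", index=False)

            p = pca(means, trait_names)
            p.scores.assign(strain=means["strain"], must=means["must"]).to_csv(
                out / "pca_scores.csv", index=False
            )
            p.loadings.to_csv(out / "pca_loadings.csv")
            p.percent_variance.rename("percent_variance").to_csv(out / "pca_variance.csv")

            classes = config.trait_classes or {"all": trait_names}
            disp = strain_dispersion(norm, classes)
            disp.to_csv(out / "strain_dispersion.csv")

            strain_means = norm.groupby("strain")[trait_names].mean()
            rc = rank_clustermap(strain_means, trait_names, max_abs_rho=1.01)
            rc.ranks.loc[list(rc.leaf_order)].to_csv(out / "rank_matrix.csv")

            n_strains = means["strain"].nunique()
            if int(config.quartile_fraction * n_strains) >= 1:
                rob = robustness_analysis(
                    means, trait_names, quartile_fraction=config.quartile_fraction,
                    alpha=config.alpha,
                )
                rob.variance.to_csv(out / "robustness_variance.csv")
                rob.fluctuating.to_csv(out / "robustness_fluctuating.csv")
                rob.group_means.to_csv(out / "robustness_group_means.csv", index=False)
                rob.wilcoxon.to_csv(out / "robustness_wilcoxon.csv", index=False)
            else:
                logger.info("stage robustness skipped: only %d strains", n_strains)
                pd.DataFrame().to_csv(out / "robustness_variance.csv")

        logger.info("pipeline complete: outputs in %s", out)
    except Exception:
        logger.exception("pipeline aborted")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
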