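"""Readers, writers, configuration and the five-stage pipeline runner.

All artifacts are plain delimited text with headers: a response file
(``person_id`` first column, item ids as headers), an item-bank file
(``item_id,scale,alpha,beta1,beta2``, with a JSON mirror), and a covariate
file (``person_id,sex,age``). The pipeline executes the five analysis
stages in order — descriptives, assumption checks, GRM calibration, DIF
screening, CAT simulation — writing one artifact per stage plus a summary.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assumptions as asm
from . import cat as cat_mod
from . import descriptives as desc
from .bank import GrmItem, ItemBank
from .dif import dif_screen, dif_table
from .grm import fit_grm_mml
from .responses import ResponseMatrix

__all__ = [
    "read_responses",
    "write_responses",
    "read_bank",
    "write_bank",
    "read_covariates",
    "write_covariates",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# responses
# ---------------------------------------------------------------------------

def read_responses(path, scale_map=None, delimiter: str = ",",
                   covariates_path=None) -> ResponseMatrix:
    """Parse a delimited response file with strict validation.

    Ragged rows, duplicate person/item ids and non-integer cells are
    reported with their line numbers. Empty cells become missing values.
    ``scale_map`` may be supplied later (e.g. from a bank file); until then
    every item is mapped to scale ``"all"``.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if len(header) < 2 or header[0] != "person_id":
            raise ValueError(
                f"{path}: header must start with 'person_id' followed by "
                "item ids"
            )
        item_ids = header[1:]
        dupes = {i for i in item_ids if item_ids.count(i) > 1}
        if dupes:
            raise ValueError(f"{path}: duplicated item columns {sorted(dupes)}")
        persons, rows = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(row)}"
                )
            persons.append(row[0])
            vals = []
            for col, cell in zip(item_ids, row[1:]):
                cell = cell.strip()
                if cell in ("", "NA", "nan"):
                    vals.append(np.nan)
                    continue
                try:
                    vals.append(float(int(cell)))
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer cell {cell!r} in "
                        f"column {col!r}"
                    ) from None
            rows.append(vals)
    dup_p = {p for p in persons if persons.count(p) > 1}
    if dup_p:
        raise ValueError(f"{path}: duplicated person ids {sorted(dup_p)}")
    frame = pd.DataFrame(rows, index=pd.Index(persons, name="person_id"),
                         columns=item_ids)
    if scale_map is None:
        scale_map = {i: "all" for i in item_ids}
    covs = read_covariates(covariates_path) if covariates_path else None
    rm = ResponseMatrix(frame, scale_map, covs)
    log.info("read %d persons x %d items from %s", rm.n_persons, rm.n_items,
             path)
    return rm


def write_responses(rm: ResponseMatrix, path, delimiter: str = ",") -> None:
    frame = rm.codes.copy()
    out = frame.map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.index.name = "person_id"
    out.to_csv(path, sep=delimiter)


# ---------------------------------------------------------------------------
# item banks
# ---------------------------------------------------------------------------

def read_bank(path) -> ItemBank:
    """Load a bank from delimited text or its JSON mirror (by extension).

    Rows violating the bank invariants (alpha <= 0, beta1 >= beta2) are
    rejected with their row number.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())["items"]
        rows = [(r["item_id"], r["scale"], r["alpha"], r["beta1"], r["beta2"])
                for r in records]
    else:
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"item_id", "scale", "alpha", "beta1", "beta2"}
            if reader.fieldnames is None or required - set(reader.fieldnames):
                raise ValueError(
                    f"{path}: bank header must contain {sorted(required)}"
                )
            rows = [(r["item_id"], r["scale"], r["alpha"], r["beta1"],
                     r["beta2"]) for r in reader]
    items = []
    for rownum, (iid, scale, a, b1, b2) in enumerate(rows, start=2):
        try:
            items.append(GrmItem(iid, scale, float(a), float(b1), float(b2)))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: row {rownum}: {exc}") from None
    return ItemBank(items)


def write_bank(bank: ItemBank, path, delimiter: str = ",") -> None:
    """Write a bank as delimited text, or JSON when the path ends ``.json``.
    Shortest-exact float formatting, so a round-trip reproduces every value
    (well beyond the 12 significant digits the format guarantees)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {"items": [dataclasses.asdict(it) for it in bank]}
        path.write_text(json.dumps(payload, indent=1))
        return
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["item_id", "scale", "alpha", "beta1", "beta2"])
        for it in bank:
            w.writerow([it.item_id, it.scale, repr(it.alpha),
                        repr(it.beta1), repr(it.beta2)])


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def read_covariates(path, delimiter: str = ",") -> pd.DataFrame:
    frame = pd.read_csv(path, sep=delimiter, index_col="person_id")
    if "sex" not in frame.columns or "age" not in frame.columns:
        raise ValueError(f"{path}: covariate file needs 'sex' and 'age'")
    return frame


def write_covariates(covs: pd.DataFrame, path, delimiter: str = ",") -> None:
    covs.to_csv(path, sep=delimiter, index_label="person_id")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """Flat configuration for the end-to-end pipeline.

    Thresholds default to the conventional screening values (residual
    correlation 0.2, scalability 0.3, DIF pseudo-R2 0.03); the SE grid is
    0.2..0.8 in steps of 0.1.
    """

    responses: str = ""
    covariates: str | None = None
    bank: str | None = None
    outdir: str = "out"
    delimiter: str = ","
    residual_threshold: float = asm.RESIDUAL_THRESHOLD
    h_threshold: float = asm.H_THRESHOLD
    dif_r2: float = 0.03
    se_grid: tuple = cat_mod.DEFAULT_SE_GRID
    max_items_half: bool = True
    seed: int = 0
    stages: tuple = ("describe", "assumptions", "grm", "dif", "cat")

    def validate(self) -> None:
        if not self.responses:
            raise ValueError("config must name a responses file")
        grid = list(self.se_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("se_grid must be strictly increasing")
        if self.residual_threshold <= 0 or self.h_threshold <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "se_grid" in data:
            data["se_grid"] = tuple(data["se_grid"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _fmt(frame: pd.DataFrame) -> pd.DataFrame:
    return frame.map(lambda v: float(f"{v:.6g}")
                     if isinstance(v, float) and np.isfinite(v) else v)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order, writing one artifact each.

    Stage failures are isolated: later stages that do not depend on the
    failed one still run, and every failure is recorded in the summary. The
    run is deterministic given its inputs. Returns the report bundle (also
    written as ``summary.json``).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in vars(config).items()},
                    "errors": {}}

    bank = read_bank(config.bank) if config.bank else None
    scale_map = bank.scale_map if bank else None
    rm = read_responses(config.responses, scale_map=scale_map,
                        delimiter=config.delimiter,
                        covariates_path=config.covariates)
    rm, excluded = desc.complete_cases(rm)
    pd.Series(excluded, name="person_id").to_csv(
        outdir / "excluded_persons.csv", index=False)
    report["n_retained"] = rm.n_persons
    report["n_excluded"] = len(excluded)
    report["retention_percent"] = desc.retention_percent(
        rm.n_persons, rm.n_persons + len(excluded))

    scales = rm.scales

    if "describe" in config.stages:
        try:
            rows = [desc.scale_summary(rm, s).to_row() for s in scales]
            frame = pd.DataFrame(rows)
            _fmt(frame).to_csv(outdir / "step1_descriptives.csv", index=False)
            report["descriptives"] = rows
        except Exception as exc:
            report["errors"]["describe"] = str(exc)
            log.exception("describe stage failed")

    if "assumptions" in config.stages:
        try:
            fit_rows, flagged_all, h_rows = [], [], []
            for s in scales:
                R = asm.polychoric_matrix(rm, s)
                _, fit, resid = asm.fit_one_factor(R, rm.n_persons)
                fit_rows.append({"scale": s, "cfi": fit.cfi, "tli": fit.tli,
                                 "rmsea": fit.rmsea, "srmr": fit.srmr,
                                 "all_good": fit.all_good})
                for a, b, r in asm.flag_local_dependence(
                        resid, config.residual_threshold):
                    flagged_all.append({"scale": s, "item_a": a, "item_b": b,
                                        "residual": r})
                sc = asm.scalability(rm, s)
                for iid, h in sc.item_h.items():
                    h_rows.append({"scale": s, "item_id": iid, "H": h,
                                   "above_threshold": h > config.h_threshold})
            _fmt(pd.DataFrame(fit_rows)).to_csv(
                outdir / "step2_fit_indices.csv", index=False)
            pd.DataFrame(flagged_all,
                         columns=["scale", "item_a", "item_b", "residual"]
                         ).to_csv(outdir / "step2_flagged_pairs.csv",
                                  index=False)
            _fmt(pd.DataFrame(h_rows)).to_csv(
                outdir / "step2_scalability.csv", index=False)
            report["fit_indices"] = fit_rows
            report["flagged_pairs"] = flagged_all
            report["pair_count"] = asm.count_item_pairs(
                [len(rm.items_in(s)) for s in scales])
        except Exception as exc:
            report["errors"]["assumptions"] = str(exc)
            log.exception("assumptions stage failed")

    calibrated = bank
    if "grm" in config.stages:
        try:
            fitted_items, diag_frames = [], []
            for s in scales:
                fit = fit_grm_mml(rm, s)
                fitted_items.extend(fit.bank.items)
                diag_frames.append(fit.diagnostics.assign(scale=s))
            calibrated = ItemBank(fitted_items)
            write_bank(calibrated, outdir / "step3_bank.csv")
            _fmt(pd.concat(diag_frames)).to_csv(
                outdir / "step3_diagnostics.csv")
            report["crc_anomalies"] = [
                i for f in diag_frames for i in f.index[f["crc_anomaly"]]
            ]
        except Exception as exc:
            report["errors"]["grm"] = str(exc)
            log.exception("grm stage failed")

    if "dif" in config.stages:
        if calibrated is None:
            report["errors"]["dif"] = (
                "DIF needs a calibrated bank: supply one or enable the grm "
                "stage"
            )
        elif rm.covariates is None:
            report["errors"]["dif"] = "no covariate file supplied"
        else:
            try:
                results = dif_screen(rm, calibrated)
                _fmt(dif_table(results)).to_csv(outdir / "step4_dif.csv",
                                                index=False)
                report["dif_flagged"] = [
                    f"{r.item_id}:{r.covariate}" for r in results if r.flagged
                ]
            except Exception as exc:
                report["errors"]["dif"] = str(exc)
                log.exception("dif stage failed")

    if "cat" in config.stages:
        if calibrated is None:
            report["errors"]["cat"] = (
                "CAT needs a calibrated bank: supply one or enable the grm "
                "stage"
            )
        else:
            try:
                banks = {s: calibrated.subset(s) for s in scales}
                rms = {s: rm for s in scales}
                for s in scales:
                    tab = cat_mod.se_grid(banks[s], rm, config.se_grid)
                    _fmt(tab).to_csv(outdir / f"step5_segrid_{s}.csv",
                                     index=False)
                flags = {s: config.max_items_half for s in scales}
                combined = cat_mod.combined_rule_report(
                    banks, rms, flags, config.se_grid)
                _fmt(combined.to_frame()).to_csv(
                    outdir / "step5_combined.csv", index=False)
                report["cat"] = {
                    "total_full": combined.total_full,
                    "total_cat": combined.total_cat,
                    "reduction_percent": combined.reduction_percent,
                }
            except Exception as exc:
                report["errors"]["cat"] = str(exc)
                log.exception("cat stage failed")

    (outdir / "summary.json").write_text(
        json.dumps(report, indent=1, default=str))
    return report
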