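"""Pipeline orchestration: run the analysis stages from one configuration.

A RunConfig points at whatever inputs are available — an aligned FASTA plus
reference id, a PDB structure, a role TSV, hemolysis trace CSVs, a
dose–response CSV, melting CSVs — and ``run`` executes every stage whose
inputs are present, in dependency order, collecting the results into a
machine-readable report (JSON plus TSV/CSV tables). A stage failure is
recorded in the report without aborting the other stages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import conservation, crosstab, kinetics, melting, sequences, structure

log = logging.getLogger("actinovar")


@dataclass
class RunConfig:
    alignment: str | None = None      # aligned FASTA
    reference_id: str | None = None
    structure_path: str | None = None  # PDB
    chain: str | None = None
    roles: str | None = None          # TSV position\trole
    traces: list[str] = field(default_factory=list)   # CSV time_s,a700
    dose_response: str | None = None  # CSV conc_nM,hemolysis_pct
    melts: list[str] = field(default_factory=list)    # CSV temp_C,signal
    probe_radius: float = structure.DEFAULT_PROBE
    n_points: int = structure.DEFAULT_N_POINTS
    low_threshold: float = structure.LOW_THRESHOLD
    high_threshold: float = structure.HIGH_THRESHOLD
    melt_window: int = 10
    out_dir: str = "actinovar_out"


def _stage(report: dict, name: str):
    """Record stage success/failure without aborting the pipeline."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                log.error("stage %s failed: %s", name, exc)
                report["stages"][name] = {"status": "failed", "error": str(exc)}
                return True
            if name not in report["stages"]:
                report["stages"][name] = {"status": "ok"}
            return False
    return _Ctx()


def run(config: RunConfig) -> dict:
    """Execute all stages whose inputs are configured; write a report bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "parameters": {
        k: v for k, v in asdict(config).items()}}
    cons_map = None
    asa_entries = None
    ref_seq = None

    if config.alignment:
        with _stage(report, "conservation"):
            aln = conservation.Alignment(rows=tuple(
                sequences.read_fasta(config.alignment)))
            profile = conservation.conservation_profile(aln)
            ref_id = config.reference_id or aln.rows[0].id
            cons_map = conservation.map_to_reference(aln, ref_id)
            ref_seq = aln.row(ref_id).ungapped()
            pd.DataFrame(conservation.profile_table(aln),
                         columns=["column", "residues", "category"]).to_csv(
                out_dir / "conservation.tsv", sep="\t", index=False)
            report["stages"]["conservation"] = {
                "status": "ok", "n_cols": aln.n_cols, "reference": ref_id,
                "profile": profile,
                "category_counts": {c.value: sum(v is c for v in cons_map.values())
                                    for c in conservation.ConservationCategory}}

    if config.structure_path:
        with _stage(report, "asa"):
            atoms = structure.read_structure(config.structure_path, chain=config.chain)
            entries = structure.asa_table(atoms, probe_radius=config.probe_radius,
                                          n_points=config.n_points,
                                          low=config.low_threshold,
                                          high=config.high_threshold)
            asa_entries = entries
            pd.DataFrame([{"chain": e.chain, "resnum": e.residue_number,
                           "resname": e.residue_name,
                           "sidechain_asa": round(e.sidechain_asa, 2),
                           "ratio": round(e.ratio, 4), "class": e.asa_class.value}
                          for e in entries]).to_csv(out_dir / "asa.tsv", sep="\t",
                                                    index=False)
            report["stages"]["asa"] = {
                "status": "ok", "n_residues": len(entries),
                "class_counts": {c.value: sum(e.asa_class is c for e in entries)
                                 for c in structure.ASAClass}}

    if config.roles and cons_map is not None and asa_entries is not None:
        with _stage(report, "crosstab"):
            roles = crosstab.read_roles(config.roles)
            joined = crosstab.build_records(cons_map, asa_entries, roles,
                                            reference_seq=ref_seq)
            summary = crosstab.summarize(joined.records)
            for scope in ("all", "none", "lipid", "ppi"):
                crosstab.crosstab(joined.records, scope).to_csv(
                    out_dir / f"crosstab_{scope}.csv")
            report["stages"]["crosstab"] = {
                "status": "ok",
                "missing_from_structure": joined.missing_from_structure,
                **{k: v for k, v in summary.items() if not k.startswith("crosstab_")}}

    if config.traces:
        with _stage(report, "kinetics"):
            results = []
            for path in config.traces:
                df = pd.read_csv(path)
                trace = kinetics.HemolysisTrace(
                    time=df.iloc[:, 0].to_numpy(), absorbance=df.iloc[:, 1].to_numpy())
                r = kinetics.analyze_trace(trace)
                results.append({"trace": str(path), "lysed": r.lysed,
                                "lag_s": r.lag_time, "vmax_per_s": r.vmax})
            report["stages"]["kinetics"] = {"status": "ok", "traces": results}
            lysing = [(res["trace"], res["lag_s"]) for res in results if res["lysed"]]
            report["stages"]["kinetics"]["n_lysing"] = len(lysing)

    if config.dose_response:
        with _stage(report, "dose_response"):
            df = pd.read_csv(config.dose_response)
            fit = kinetics.fit_hill(list(zip(df.iloc[:, 0], df.iloc[:, 1])))
            report["stages"]["dose_response"] = {
                "status": "ok", "hc50_nM": fit.hc50, "hill_n": fit.hill_n,
                "plateau_pct": fit.plateau, "extrapolated": fit.extrapolated}

    if config.melts:
        with _stage(report, "melting"):
            results = []
            for path in config.melts:
                df = pd.read_csv(path)
                curve = melting.MeltingCurve(temperature=df.iloc[:, 0].to_numpy(),
                                             signal=df.iloc[:, 1].to_numpy())
                r = melting.melting_temperature(curve, window=config.melt_window)
                results.append({"melt": str(path), "transition": r.transition,
                                "tm_C": r.tm})
            report["stages"]["melting"] = {"status": "ok", "melts": results}

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
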