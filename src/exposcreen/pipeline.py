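"""End-to-end orchestration: read -> QC filter -> annotate -> levels ->
statistics -> overlap -> pathway ORA.

Stage order is fixed (QC filtering precedes both annotation and
statistics).  Every output row is traceable to a feature id; all outputs
are CSV plus a MANIFEST with file hashes and the full threshold echo, and
a structured log line per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import IsotopePattern
from .config import RunConfig
from .levels import SCHEMES
from .msdata import CohortDesign, Feature, Spectrum, read_feature_table, read_msp, read_suspect_list
from .overlap import overlap, pathway_ora
from .qc import qc_rsd_filter, qc_stats_frame
from .stats import ProcessedMatrix, iqr_filter, normalize_and_scale, plsda_vip, select_significant, univariate
from .suspects import AnnotationEvidence, build_evidence, merge_hits_across_lists, screen_suspects

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_dataset"]

STAGES = ["qc", "annotate", "levels", "stats", "overlap", "ora"]


def load_dataset(dataset_dir: str | Path) -> dict:
    """Load a dataset directory as written by the cohort generator."""
    d = Path(dataset_dir)
    design = CohortDesign.from_csv(d / "design.csv")
    features = read_feature_table(d / "feature_table.csv", design)
    ms2 = {s.name: s for s in read_msp(d / "ms2.msp")} if (d / "ms2.msp").exists() else {}
    for f in features:
        if f.feature_id in ms2:
            f.ms2 = ms2[f.feature_id]
    libraries = {"+": [], "-": []}
    if (d / "library_pos.msp").exists():
        libraries["+"] = read_msp(d / "library_pos.msp")
    if (d / "library_neg.msp").exists():
        libraries["-"] = read_msp(d / "library_neg.msp")
    suspect_lists = {}
    for p in sorted(d.glob("suspects_*.csv")):
        code = p.stem.replace("suspects_", "")
        suspect_lists[code] = read_suspect_list(p, code)
    observed_iso: dict[str, IsotopePattern] = {}
    if (d / "isotopes.csv").exists():
        iso_df = pd.read_csv(d / "isotopes.csv")
        for _, row in iso_df.iterrows():
            ab = [float(x) for x in str(row["abundances"]).split(";")]
            observed_iso[str(row["feature_id"])] = IsotopePattern(
                tuple((float(k) * 1.0033548378, a) for k, a in enumerate(ab))
            )
    pathways: dict[str, list[str]] = {}
    if (d / "pathways.csv").exists():
        pw = pd.read_csv(d / "pathways.csv")
        for _, row in pw.iterrows():
            pathways.setdefault(str(row["pathway_id"]), []).append(str(row["member"]))
    return {
        "design": design,
        "features": features,
        "libraries": libraries,
        "suspect_lists": suspect_lists,
        "observed_iso": observed_iso,
        "pathways": pathways,
    }


def _annotation_row(f: Feature, ev: AnnotationEvidence) -> dict:
    top = ev.top_formula
    return {
        "feature_id": f.feature_id,
        "mz": f.mz,
        "rt": f.rt,
        "esi_mode": f.esi_mode,
        "lc_mode": f.lc_mode,
        "library_match": ev.library_match_name,
        "inchikey": ev.library_match_inchikey,
        "library_score": ev.library_score,
        "dot_product": ev.dot_product,
        "fragment_presence": ev.fragment_presence,
        "n_matched_fragments": ev.n_matched_fragments,
        "candidate_count": ev.candidate_count,
        "structure_known": ev.structure_known,
        "top_formula": top.formula.hill() if top else None,
        "formula_ppm_error": top.ppm_error if top else None,
        "iso_score": top.iso_score if top else None,
        "ann_sim_form": top.ann_sim_form if top else None,
        "ann_sim_comp": top.ann_sim_comp if top else None,
        "gap_iso": top.gap_iso if top else None,
        "gap_ann": top.gap_ann if top else None,
    }


def run_pipeline(config: RunConfig, through_stage: str = "ora") -> dict:
    """Run the chain up to ``through_stage``, writing outputs to
    ``config.out_dir``.  Returns the in-memory stage products."""
    if through_stage not in STAGES:
        raise ValueError(f"unknown stage {through_stage!r}")
    last = STAGES.index(through_stage)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log_stage(name: str, **info) -> None:
        line = f"stage={name} " + " ".join(f"{k}={v}" for k, v in info.items())
        log_lines.append(line)
        logger.info(line)

    t0 = time.time()
    data = load_dataset(config.dataset_dir)
    design: CohortDesign = data["design"]
    features: list[Feature] = data["features"]
    log_stage("load", n_features=len(features), n_samples=len(design.groups))

    results: dict = {"data": data}

    # --- qc ---------------------------------------------------------------
    retained, qc_stats = qc_rsd_filter(features, design, config.qc_rsd_max_pct)
    qc_stats_frame(qc_stats).to_csv(out / "qc_stats.csv", index=False)
    log_stage("qc", n_in=len(features), n_out=len(retained), rsd_max=config.qc_rsd_max_pct)
    results["retained"] = retained
    results["qc_stats"] = qc_stats

    # --- annotate ---------------------------------------------------------
    if last >= STAGES.index("annotate"):
        evidence: dict[str, AnnotationEvidence] = {}
        for f in retained:
            evidence[f.feature_id] = build_evidence(
                f,
                data["libraries"].get(f.esi_mode, []),
                data["observed_iso"].get(f.feature_id),
                tol_ppm=config.ms1_tol_ppm,
                ms2_tol_mz=config.ms2_tol_mz,
                rel_int_floor=config.ms2_rel_int_floor,
                element_bounds=config.element_bounds,
            )
        ann_df = pd.DataFrame([_annotation_row(f, evidence[f.feature_id]) for f in retained])
        results["evidence"] = evidence

        hits = screen_suspects(
            retained,
            list(data["suspect_lists"].values()),
            adduct_set=config.adduct_set,
            tol_ppm=config.ms1_tol_ppm,
            library=data["libraries"]["+"] + data["libraries"]["-"],
            observed_iso=data["observed_iso"],
            ms2_tol_mz=config.ms2_tol_mz,
            element_bounds=config.element_bounds,
        )
        hit_df = pd.DataFrame(
            [
                {
                    "feature_id": h.feature_id,
                    "name": h.suspect.name,
                    "list_code": h.suspect.list_code,
                    "adduct": h.adduct.name,
                    "ppm_error": h.ppm_error,
                    "library_score": h.evidence.library_score,
                }
                for h in hits
            ]
        )
        hit_df.to_csv(out / "suspect_hits.csv", index=False)
        merge_hits_across_lists(hits).to_csv(out / "suspect_hits_merged.csv", index=False)
        log_stage("annotate", n_features=len(retained), n_suspect_hits=len(hits))
        results["hits"] = hits

    # --- levels -----------------------------------------------------------
    if last >= STAGES.index("levels"):
        suspect_fids = {h.feature_id for h in results["hits"]}
        for scheme in config.schemes:
            assign = SCHEMES[scheme]
            col, rule_col = [], []
            for f in retained:
                # the suspect scheme only applies to suspect-screening hits
                if scheme == "suspect_patroon" and f.feature_id not in suspect_fids:
                    col.append(None)
                    rule_col.append(None)
                    continue
                lvl = assign(results["evidence"][f.feature_id])
                col.append(lvl.value)
                rule_col.append(lvl.fired_rule)
            ann_df[f"level_{scheme}"] = col
            ann_df[f"rule_{scheme}"] = rule_col
        ann_df.to_csv(out / "annotation.csv", index=False)
        level_counts = {
            scheme: ann_df[f"level_{scheme}"].value_counts().to_dict() for scheme in config.schemes
        }
        log_stage("levels", **{s: sum(c.values()) for s, c in level_counts.items()})
        results["annotation"] = ann_df
        results["level_counts"] = level_counts

    # --- stats ------------------------------------------------------------
    if last >= STAGES.index("stats"):
        mat = pd.DataFrame(
            {s: [f.intensities.get(s, 0.0) for f in retained] for s in design.groups},
            index=[f.feature_id for f in retained],
        )
        raw = ProcessedMatrix(mat, "raw", design)
        filtered = iqr_filter(raw)
        normalized, scaled = normalize_and_scale(filtered)
        uni = univariate(normalized, scaled)
        vip = plsda_vip(scaled, orthogonal=config.stats_orthogonal)
        selection, volcano = select_significant(
            uni,
            vip,
            p_max=config.stats_p_max,
            fc_up=config.stats_fc_up,
            fc_down=config.stats_fc_down,
            vip_min=config.stats_vip_min,
            fdr=config.stats_fdr,
        )
        sel_df = pd.DataFrame(
            [
                {
                    "feature_id": r.feature_id,
                    "fold_change": r.fold_change,
                    "p_value": r.p_value,
                    "vip": r.vip,
                    "significant": r.significant,
                    "direction": r.direction,
                }
                for r in selection
            ]
        )
        sel_df.to_csv(out / "selection.csv", index=False)
        volcano.to_csv(out / "volcano.csv")
        log_stage(
            "stats",
            n_tested=len(sel_df),
            n_significant=int(sel_df["significant"].sum()),
            p_max=config.stats_p_max,
        )
        results["selection"] = selection
        results["selection_df"] = sel_df

    # --- overlap ----------------------------------------------------------
    if last >= STAGES.index("overlap"):
        ann = results["annotation"]
        keyed = ann[ann["inchikey"].notna()]
        excluded = set(ann.loc[ann["inchikey"].isna(), "feature_id"])
        reports = {}
        for axis, col in (("esi", "esi_mode"), ("lc", "lc_mode")):
            sets = {
                str(v): set(keyed.loc[keyed[col] == v, "inchikey"]) for v in keyed[col].unique()
            }
            if len(sets) >= 2:
                rep = overlap(sets, excluded=excluded)
                rep.to_frame().to_csv(out / f"overlap_{axis}.csv", index=False)
                reports[axis] = rep
        log_stage("overlap", axes=",".join(reports))
        results["overlap"] = reports

    # --- ora --------------------------------------------------------------
    if last >= STAGES.index("ora"):
        ann = results["annotation"]
        hits_by_fid: dict[str, str] = {}
        for h in results["hits"]:
            hits_by_fid.setdefault(h.feature_id, h.suspect.name)
        names = {}
        for _, row in ann.iterrows():
            name = row["library_match"] or hits_by_fid.get(row["feature_id"])
            if name:
                names[row["feature_id"]] = name
        universe = sorted(set(names.values()))
        sig_fids = {r.feature_id for r in results["selection"] if r.significant}
        selected = sorted({names[fid] for fid in sig_fids if fid in names})
        ora = pathway_ora(selected, universe, data["pathways"]) if universe else []
        pd.DataFrame(
            [
                {
                    "pathway_id": r.pathway_id,
                    "hits": r.hits,
                    "pathway_size": r.pathway_size,
                    "universe_size": r.universe_size,
                    "selected_size": r.selected_size,
                    "p_value": r.p_value,
                }
                for r in ora
            ]
        ).to_csv(out / "ora.csv", index=False)
        log_stage("ora", n_pathways=len(ora), n_selected_names=len(selected))
        results["ora"] = ora

    # --- provenance --------------------------------------------------------
    logger.info("pipeline finished in %.2f s", time.time() - t0)
    log_stage("done", n_stages=last + 1)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    manifest = {"config": config.to_dict(), "files": {}}
    for p in sorted(out.iterdir()):
        if p.name == "MANIFEST.json":
            continue
        manifest["files"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return results
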