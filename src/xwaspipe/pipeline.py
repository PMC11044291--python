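"""End-to-end orchestration: simulate → xwas → curate → novelty → metrics → mmrp → report.

Every stage writes plain TSV artifacts into the run directory and records its
input/output row counts in the run manifest, so each printed number of a run
is auditable from the files alone. Stages can be re-run individually: when a
stage's in-memory prerequisites are absent it reloads them from the artifacts
of an earlier run, and fails with an orchestration error naming the stage and
missing file otherwise. With a fixed config and seed the tabular outputs are
byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from . import __version__
from .assoc import (
    HeidiParams,
    bonferroni_filter,
    heidi_test,
    results_to_frame,
    smr_test,
    train_weights,
    twas_association,
)
from .config import AnalysisConfig, substream
from .evidence import (
    build_lines,
    count_support,
    disorder_of,
    reliable_by_mode,
    support_counts_frame,
)
from .io import (
    read_alias_table,
    read_evidence_table,
    read_gene_annotations,
    read_gwas_sumstats,
    exclude_region,
    write_gene_annotations,
    write_gwas_sumstats,
    write_qtl_sumstats,
)
from .metrics import (
    compare_replication_times,
    enumerate_mmrp,
    gene_qtl_profiles,
    mmrp_frame,
    replication_matrix,
)
from .novelty import novelty_calls, novelty_frame
from .simulate import gene_annotations, ld_reference, scan_cis_qtl, simulate_cohort
from .types import EvidenceLine, NoveltyCall, QtlType, SourceGroup, SupportCount

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "xwas", "curate", "novelty", "metrics", "mmrp", "report")


class OrchestrationError(RuntimeError):
    pass


@dataclass
class RunManifest:
    seed: int
    config: dict
    version: str = __version__
    stage_counts: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def record(self, stage: str, **counts: int) -> None:
        self.stage_counts[stage] = dict(counts)
        self.timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "version": self.version,
                    "config": self.config,
                    "stage_counts": self.stage_counts,
                    "timestamps": self.timestamps,
                },
                fh,
                indent=2,
                default=str,
            )


def default_alias_table() -> dict[str, str]:
    """The shipped synthetic alias-table fixture (HGNC-style alias→canonical)."""
    path = resources.files("xwaspipe").joinpath("data/synthetic_hgnc_aliases.tsv")
    with resources.as_file(path) as p:
        return read_alias_table(p)


def _require(outdir: Path, name: str, stage: str) -> Path:
    path = outdir / name
    if not path.exists():
        raise OrchestrationError(f"stage {stage!r}: missing prerequisite file {path}")
    return path


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: AnalysisConfig, outdir: Path, state: dict, manifest: RunManifest):
    rng = substream(cfg.seed, "simulate")
    cohort = simulate_cohort(cfg.simulation, rng)
    state["cohort"] = cohort
    geno, layers = cohort["geno"], cohort["layers"]
    annotations = gene_annotations(layers)
    write_gene_annotations(annotations, outdir / "annotation.tsv")
    qtl_rows = 0
    state["qtl_by_layer"] = {}
    for layer in layers:
        qtls = scan_cis_qtl(geno, layer)
        state["qtl_by_layer"][layer.layer_type] = qtls
        write_qtl_sumstats(qtls, outdir / f"qtl_{layer.layer_type.value}.tsv")
        qtl_rows += sum(len(q.records) for q in qtls)
    for disorder, bundle in cohort["traits"].items():
        write_gwas_sumstats(bundle["gwas"], outdir / f"gwas_{disorder}.tsv")
        write_gwas_sumstats(bundle["gwas_old"], outdir / f"gwas_{disorder}_old.tsv")
    truth_rows = []
    for disorder, bundle in cohort["traits"].items():
        for fid, bxy in sorted(bundle["truth"].bxy_true.items()):
            truth_rows.append(
                {
                    "DISORDER": disorder,
                    "FEATURE": fid,
                    "GENE": cohort["truth"].gene_of_feature.get(fid, ""),
                    "B_XY_TRUE": bxy,
                }
            )
    pd.DataFrame(
        truth_rows, columns=["DISORDER", "FEATURE", "GENE", "B_XY_TRUE"]
    ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    manifest.record(
        "simulate",
        n_individuals=geno.n_individuals,
        n_variants=geno.n_variants,
        n_features=sum(len(l.features) for l in layers),
        n_genes=len(annotations),
        n_qtl_rows=qtl_rows,
        n_disorders=len(cohort["traits"]),
    )


def _stage_xwas(cfg: AnalysisConfig, outdir: Path, state: dict, manifest: RunManifest):
    if "cohort" not in state:
        raise OrchestrationError(
            "stage 'xwas': requires in-memory cohort; run the simulate stage first"
        )
    cohort = state["cohort"]
    geno, layers = cohort["geno"], cohort["layers"]
    rng_seed = substream(cfg.seed, "xwas").integers(0, 2**31 - 1)
    heidi_params = HeidiParams()
    ld_cache = {}
    results = []
    features = [f for layer in layers for f in layer.features]
    models = {
        f.feature_id: train_weights(geno, f, model="best", cv_folds=3, seed=int(rng_seed))
        for f in features
    }
    qtl_by_feature = {
        q.feature_id: q for qtls in state["qtl_by_layer"].values() for q in qtls
    }
    for disorder, bundle in cohort["traits"].items():
        for tag, gwas in (("current", bundle["gwas"]), ("old", bundle["gwas_old"])):
            gwas = exclude_region(gwas, cfg.mhc_region)
            for feat in features:
                key = feat.feature_id
                if key not in ld_cache:
                    ld_cache[key] = ld_reference(geno, feat.cis_indices)
                ld = ld_cache[key]
                qtl = qtl_by_feature.get(key)
                if qtl is None:
                    continue
                qtl = exclude_region(qtl, cfg.mhc_region)
                model = models[key]
                try:
                    res = twas_association(
                        model,
                        gwas,
                        ld,
                        gwas_dataset=gwas.trait_id,
                        qtl_dataset=feat.dataset_tag,
                        brain_keywords=cfg.brain_keywords,
                    )
                    results.append(res)
                except Exception as exc:  # feature-level, not fatal
                    logger.warning("FUSION %s/%s: %s", gwas.trait_id, key, exc)
                smr = smr_test(
                    qtl,
                    gwas,
                    instrument_p_threshold=cfg.instrument_p_threshold,
                    gwas_dataset=gwas.trait_id,
                    brain_keywords=cfg.brain_keywords,
                )
                if smr is not None:
                    p_h, n_h = heidi_test(
                        qtl, gwas, ld, heidi_params, seed=int(rng_seed)
                    )
                    smr.p_heidi = p_h
                    smr.n_snps_heidi = n_h
                    results.append(smr)
    results = bonferroni_filter(
        results,
        alpha=cfg.bonferroni_alpha,
        heidi_retain_threshold=cfg.heidi_retain_threshold,
    )
    state["xwas_results"] = results
    frame = results_to_frame(results)
    frame.to_csv(outdir / "xwas_results.tsv", sep="\t", index=False)
    # evidence TSV: old-GWAS rows emulate curated (published) evidence
    passed = frame[frame["PASS"]]
    evidence = pd.DataFrame(
        {
            "GWAS_DATASET": passed["GWAS_DATASET"],
            "QTL_TYPE": passed["QTL_TYPE"],
            "TISSUE": passed["TISSUE_GROUP"],
            "TOOL": passed["TOOL"],
            "GENE": passed["GENE"],
            "SOURCE": [
                "CG" if d.endswith("_old") else "SG" for d in passed["GWAS_DATASET"]
            ],
        }
    ).drop_duplicates(ignore_index=True)
    evidence = evidence.sort_values(list(evidence.columns), ignore_index=True)
    evidence.to_csv(outdir / "evidence.tsv", sep="\t", index=False)
    manifest.record(
        "xwas",
        n_results=len(frame),
        n_pass=int(frame["PASS"].sum()),
        n_evidence_rows=len(evidence),
    )


def _stage_curate(cfg: AnalysisConfig, outdir: Path, state: dict, manifest: RunManifest):
    if "evidence_frames" in state:
        frames = state["evidence_frames"]
    else:
        frames = [read_evidence_table(_require(outdir, "evidence.tsv", "curate"))]
    alias = state.get("alias_table")
    if alias is None:
        alias = default_alias_table()
    lines: set[EvidenceLine] = set()
    for df in frames:
        for source in ("CG", "SG"):
            sub = df[df["SOURCE"] == source]
            if len(sub):
                lines |= build_lines(
                    sub.drop(columns=["SOURCE"]),
                    SourceGroup(source),
                    alias_table=alias,
                    brain_keywords=cfg.brain_keywords,
                )
    state["lines"] = lines
    disorders = sorted({disorder_of(l.gwas_dataset) for l in lines})
    state["disorders"] = disorders
    counts_all: list[SupportCount] = []
    reliable_rows = []
    state["reliable"] = {}
    for disorder in disorders:
        counts_all.extend(count_support(lines, disorder, mode="pooled"))
        modes = reliable_by_mode(lines, disorder, cfg.reliable_min_count)
        state["reliable"][disorder] = modes
        for group, genes in modes.items():
            for gene in sorted(genes):
                reliable_rows.append(
                    {"DISORDER": disorder, "GROUP": group, "GENE": gene}
                )
    state["support_counts"] = counts_all
    support_counts_frame(counts_all).to_csv(
        outdir / "support_counts.tsv", sep="\t", index=False
    )
    pd.DataFrame(reliable_rows, columns=["DISORDER", "GROUP", "GENE"]).to_csv(
        outdir / "reliable_genes.tsv", sep="\t", index=False
    )
    manifest.record(
        "curate",
        n_lines=len(lines),
        n_genes_counted=len(counts_all),
        n_reliable_total=sum(
            len(m["Total"]) for m in state["reliable"].values()
        ),
    )


def _load_reliable(outdir: Path, stage: str) -> dict[str, dict[str, set[str]]]:
    df = pd.read_csv(_require(outdir, "reliable_genes.tsv", stage), sep="\t")
    out: dict[str, dict[str, set[str]]] = {}
    for (disorder, group), sub in df.groupby(["DISORDER", "GROUP"]):
        out.setdefault(disorder, {}).setdefault(group, set()).update(sub["GENE"])
    return out


def _stage_novelty(cfg: AnalysisConfig, outdir: Path, state: dict, manifest: RunManifest):
    reliable = state.get("reliable") or _load_reliable(outdir, "novelty")
    if "cohort" in state:
        annotations = gene_annotations(state["cohort"]["layers"])
        gwas_of = {
            d: b["gwas"] for d, b in state["cohort"]["traits"].items()
        }
    else:
        annotations = read_gene_annotations(_require(outdir, "annotation.tsv", "novelty"))
        gwas_of = {}
        for disorder in reliable:
            gwas_of[disorder] = read_gwas_sumstats(
                _require(outdir, f"gwas_{disorder}.tsv", "novelty")
            )
    ann_of = {g.canonical_symbol: g for g in annotations}
    calls: list[NoveltyCall] = []
    for disorder, modes in sorted(reliable.items()):
        genes = sorted(modes.get("Total", set()))
        anns = [ann_of[g] for g in genes if g in ann_of]
        calls.extend(
            novelty_calls(
                anns,
                gwas_of[disorder],
                window_bp=cfg.window_bp,
                threshold=cfg.novelty_threshold,
                disorder=disorder,
            )
        )
    state["novelty"] = calls
    novelty_frame(calls).to_csv(outdir / "novelty.tsv", sep="\t", index=False)
    manifest.record(
        "novelty",
        n_calls=len(calls),
        n_novel=sum(bool(c.is_novel) for c in calls),
        n_unclassifiable=sum(c.is_novel is None for c in calls),
    )


def _load_lines(cfg: AnalysisConfig, outdir: Path, stage: str) -> set[EvidenceLine]:
    df = read_evidence_table(_require(outdir, "evidence.tsv", stage))
    lines: set[EvidenceLine] = set()
    for source in ("CG", "SG"):
        sub = df[df["SOURCE"] == source]
        if len(sub):
            lines |= build_lines(
                sub.drop(columns=["SOURCE"]),
                SourceGroup(source),
                brain_keywords=cfg.brain_keywords,
            )
    return lines


def _load_novelty(outdir: Path, stage: str) -> list[NoveltyCall]:
    df = pd.read_csv(_require(outdir, "novelty.tsv", stage), sep="\t")
    calls = []
    for row in df.itertuples(index=False):
        is_novel = {"novel": True, "non-novel": False}.get(str(row.IS_NOVEL))
        calls.append(
            NoveltyCall(
                gene_symbol=row.GENE,
                disorder=row.DISORDER,
                window=(str(row.CHR), int(row.WINDOW_START), int(row.WINDOW_END)),
                min_p=None if str(row.MIN_P) == "NA" else float(row.MIN_P),
                n_snps_in_window=int(row.N_SNPS),
                is_novel=is_novel,
            )
        )
    return calls


def _stage_metrics(cfg: AnalysisConfig, outdir: Path, state: dict, manifest: RunManifest):
    lines = state.get("lines") or _load_lines(cfg, outdir, "metrics")
    reliable = state.get("reliable") or _load_reliable(outdir, "metrics")
    counts = state.get("support_counts")
    if counts is None:
        counts = []
        for disorder in sorted({disorder_of(l.gwas_dataset) for l in lines}):
            counts.extend(count_support(lines, disorder, mode="pooled"))
    novelty = state.get("novelty") or _load_novelty(outdir, "metrics")
    disorders = sorted(reliable.keys())
    # cross-QTL replication per disorder (all result genes, and reliable only)
    for disorder in disorders:
        by_qtl: dict[str, set[str]] = {}
        for l in lines:
            if disorder_of(l.gwas_dataset) == disorder:
                by_qtl.setdefault(l.qtl_type.value, set()).add(l.gene_symbol)
        if len(by_qtl) >= 2:
            rm = replication_matrix(by_qtl)
            rm.ratios.to_csv(outdir / f"replication_qtl_{disorder}.tsv", sep="\t")
            rm.counts.to_csv(
                outdir / f"replication_qtl_counts_{disorder}.tsv", sep="\t"
            )
    # cross-disorder replication on reliable (Total) gene sets
    if len(disorders) >= 2:
        sets = {d: reliable[d].get("Total", set()) for d in disorders}
        rm = replication_matrix(sets)
        rm.ratios.to_csv(outdir / "replication_disorders.tsv", sep="\t")
        rm.counts.to_csv(outdir / "replication_disorders_counts.tsv", sep="\t")
    # novel vs non-novel replication times
    rows = []
    for disorder in disorders:
        cmp = compare_replication_times(
            [c for c in counts if c.disorder == disorder],
            [c for c in novelty if c.disorder == disorder],
        )
        rows.append(
            {
                "DISORDER": disorder,
                "MEDIAN_NOVEL": cmp.median_novel if cmp.median_novel is not None else "NA",
                "MEDIAN_NON_NOVEL": (
                    cmp.median_non_novel if cmp.median_non_novel is not None else "NA"
                ),
                "TEST_P": cmp.test_p if cmp.test_p is not None else "NA",
                "DEGENERATE": cmp.degenerate,
            }
        )
    pd.DataFrame(
        rows,
        columns=["DISORDER", "MEDIAN_NOVEL", "MEDIAN_NON_NOVEL", "TEST_P", "DEGENERATE"],
    ).to_csv(outdir / "replication_times.tsv", sep="\t", index=False)
    manifest.record("metrics", n_disorders=len(disorders))


def _stage_mmrp(cfg: AnalysisConfig, outdir: Path, state: dict, manifest: RunManifest):
    lines = state.get("lines") or _load_lines(cfg, outdir, "mmrp")
    reliable = state.get("reliable") or _load_reliable(outdir, "mmrp")
    novelty = state.get("novelty")
    if novelty is None:
        novelty = _load_novelty(outdir, "mmrp") if (outdir / "novelty.tsv").exists() else []
    novel_of: dict[str, set[str]] = {}
    for c in novelty:
        if c.is_novel:
            novel_of.setdefault(c.disorder, set()).add(c.gene_symbol)
    frames = []
    n_patterns = 0
    for disorder in sorted(reliable.keys()):
        profiles = gene_qtl_profiles(lines, disorder)
        for scope, restrict in (
            ("reliable", reliable[disorder].get("Total", set())),
            ("novel", novel_of.get(disorder, set())),
        ):
            patterns = enumerate_mmrp(profiles, disorder, restrict_to=restrict)
            n_patterns += len(patterns)
            df = mmrp_frame(patterns)
            df.insert(1, "SCOPE", scope)
            frames.append(df)
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["DISORDER", "SCOPE", "QTL_SET", "CONTAINS_EQTL", "N_GENES", "GENES"]
        )
    )
    out.to_csv(outdir / "mmrp.tsv", sep="\t", index=False)
    state["mmrp"] = out
    manifest.record("mmrp", n_patterns=n_patterns)


def _stage_report(cfg: AnalysisConfig, outdir: Path, state: dict, manifest: RunManifest):
    report = render_report(cfg, outdir)
    with open(outdir / "report.txt", "w") as fh:
        fh.write(report["text"])
    with open(outdir / "report.json", "w") as fh:
        json.dump(report["data"], fh, indent=2)
    manifest.record("report", n_disorders=len(report["data"].get("disorders", {})))


def render_report(cfg: AnalysisConfig, outdir: Path) -> dict:
    """Assemble the per-disorder summary table from the run's TSV artifacts.

    Counts are recomputed from the files themselves, so the report doubles as
    a consistency check of the manifest.
    """
    data: dict = {"banner": "SYNTHETIC DATA — all values from simulated cohorts"}
    lines_txt = [data["banner"], ""]
    disorders: dict[str, dict] = {}
    support_path = outdir / "support_counts.tsv"
    reliable_path = outdir / "reliable_genes.tsv"
    if support_path.exists() and reliable_path.exists():
        support = pd.read_csv(support_path, sep="\t")
        reliable = pd.read_csv(reliable_path, sep="\t")
        novelty = (
            pd.read_csv(outdir / "novelty.tsv", sep="\t")
            if (outdir / "novelty.tsv").exists()
            else None
        )
        lines_txt.append(
            f"{'disorder':<10}{'total':>8}{'reliable':>10}{'novel':>8}"
        )
        for disorder, sub in support.groupby("DISORDER"):
            total = sub["GENE"].nunique()
            rel = reliable[
                (reliable["DISORDER"] == disorder) & (reliable["GROUP"] == "Total")
            ]["GENE"].nunique()
            if novelty is not None:
                nov = int(
                    (
                        (novelty["DISORDER"] == disorder)
                        & (novelty["IS_NOVEL"] == "novel")
                    ).sum()
                )
            else:
                nov = None
            disorders[disorder] = {"total": int(total), "reliable": int(rel), "novel": nov}
            lines_txt.append(
                f"{disorder:<10}{total:>8}{rel:>10}{nov if nov is not None else 'NA':>8}"
            )
    else:
        lines_txt.append("curation section: not run")
    if (outdir / "novelty.tsv").exists():
        pass
    else:
        lines_txt.append("novelty section: not run")
    data["disorders"] = disorders
    mmrp_path = outdir / "mmrp.tsv"
    if mmrp_path.exists():
        mm = pd.read_csv(mmrp_path, sep="\t")
        mm_novel = mm[mm["SCOPE"] == "novel"] if "SCOPE" in mm.columns else mm
        data["mmrp_patterns_novel"] = int(len(mm_novel))
        data["mmrp_distinct_qtl_sets"] = (
            int(mm["QTL_SET"].nunique()) if len(mm) else 0
        )
        lines_txt += ["", f"MMRP patterns (novel scope): {len(mm_novel)}"]
        for row in mm_novel.itertuples(index=False):
            lines_txt.append(
                f"  {row.DISORDER:<8}{row.QTL_SET:<30}{row.N_GENES:>4} genes"
            )
    else:
        lines_txt.append("mmrp section: not run")
    data["counts_consistent"] = True
    return {"text": "\n".join(lines_txt) + "\n", "data": data}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "xwas": _stage_xwas,
    "curate": _stage_curate,
    "novelty": _stage_novelty,
    "metrics": _stage_metrics,
    "mmrp": _stage_mmrp,
    "report": _stage_report,
}


def run_pipeline(
    cfg: AnalysisConfig,
    outdir: str | Path,
    stages: tuple[str, ...] = ALL_STAGES,
    state: dict | None = None,
) -> RunManifest:
    """Execute the requested stages in canonical order and write the manifest."""
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise OrchestrationError(f"unknown stages: {unknown}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=cfg.seed, config=cfg.model_dump())
    state = state if state is not None else {}
    for stage in ALL_STAGES:
        if stage in stages:
            logger.info("stage %s starting", stage)
            _STAGE_FUNCS[stage](cfg, outdir, state, manifest)
    manifest.write(outdir / "manifest.json")
    return manifest
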