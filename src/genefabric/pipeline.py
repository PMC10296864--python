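"""End-to-end orchestration: normalize -> metrics -> regulation -> trajectory
-> networks -> reports, with a reproducibility manifest.

All arithmetic lives in the stage modules; the pipeline only wires their
inputs and writes TSV outputs, so every output row can be recomputed from
the stage operations alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .expression import DesignError, GeneSet, ProbeTable, gene_profiles, normalize_to_median
from .fabric import (
    coordination_score,
    cor_matrix,
    fabric_summary,
    pairs_from_matrix,
)
from .io import file_sha256, read_expression_table, read_gene_sets, write_tsv
from .networks import build_network, network_edge_table, remodeling_report
from .regulation import psr, regulation_table
from .trajectory import pathway_td_summary, trajectory_table

__all__ = ["RunConfig", "run_pipeline", "summarize_quantifiers"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    expression_path: str
    layout: dict | str
    gene_sets_path: str | None = None
    reference: str = "CO"
    contrasts: list[str] = field(default_factory=list)  # case conditions
    alpha: float = 0.05
    cor_sig_threshold: float = 0.95
    cor_ind_threshold: float = 0.05
    cor_mode: str = "gene_means"
    cor_log2: bool = True
    rev_variant: str = "sqrt"
    cut_pooling: str = "rms"
    normalize: bool = True
    seed: int = 0
    outdir: str = "genefabric_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self, conditions: list[str]) -> None:
        if self.reference not in conditions:
            raise DesignError(f"reference condition {self.reference!r} not in data")
        for c in self.contrasts:
            if c not in conditions:
                raise DesignError(f"contrast condition {c!r} not in data")


def summarize_quantifiers(
    members: set[str], regulation: pd.DataFrame, trajectories: pd.DataFrame
) -> pd.DataFrame:
    """The four per-gene quantifiers for a gene set, plus their rankings.

    One row per member present: uniform contribution (+1/-1 if
    significantly regulated, else 0), expression ratio x, WIR and TD —
    with rank columns by |x|, |WIR| and TD (1 = most affected).  Rankings
    generally disagree: x ignores the normal expression level, WIR weighs
    it in, and TD also sees variability and coordination changes.
    """
    keys = {m.upper() for m in members}
    reg = regulation[regulation["gene"].str.upper().isin(keys)].set_index("gene")
    traj = trajectories[trajectories["gene"].str.upper().isin(keys)].set_index("gene")
    genes = [g for g in reg.index if g in traj.index]
    df = pd.DataFrame(
        {
            "gene": genes,
            "uniform": [int(reg.loc[g, "direction"]) for g in genes],
            "x": [float(reg.loc[g, "x"]) for g in genes],
            "wir": [float(reg.loc[g, "wir"]) for g in genes],
            "td": [float(traj.loc[g, "td"]) for g in genes],
        }
    )
    df["rank_x"] = df["x"].abs().rank(ascending=False, method="min").astype(int)
    df["rank_wir"] = df["wir"].abs().rank(ascending=False, method="min").astype(int)
    df["rank_td"] = df["td"].rank(ascending=False, method="min").astype(int)
    return df


def _analyze(table: ProbeTable, gene_sets: list[GeneSet], config: RunConfig) -> dict:
    """Run every stage in memory; returns a dict of result objects."""
    conditions = table.conditions
    config.validate(conditions)
    if config.normalize:
        table = normalize_to_median(table)

    profiles = {c: gene_profiles(table, c) for c in conditions}
    fabric = {c: fabric_summary(profiles[c], config.rev_variant) for c in conditions}
    cors = {c: cor_matrix(profiles[c], log2=config.cor_log2) for c in conditions}

    regs = {
        case: regulation_table(
            profiles[config.reference], profiles[case], config.reference, case,
            alpha=config.alpha, cut_pooling=config.cut_pooling,
            rev_variant=config.rev_variant,
        )
        for case in config.contrasts
    }
    fab_ix = {c: fabric[c].set_index("gene") for c in conditions}
    trajs = {
        case: trajectory_table(
            fab_ix[config.reference], fab_ix[case],
            cors[config.reference], cors[case], config.reference, case,
        )
        for case in config.contrasts
    }

    set_results = []
    for gs in gene_sets:
        lookup = {g.upper(): g for g in profiles[config.reference]}
        nodes = sorted(lookup[m] for m in gs.members_upper() if m in lookup)
        if len(nodes) < 2:
            continue
        nets, coords = {}, {}
        for c in conditions:
            pairs = pairs_from_matrix(
                cors[c].loc[nodes, nodes], c,
                config.cor_sig_threshold, config.cor_ind_threshold,
            )
            coords[c] = coordination_score(gs.name, c, pairs)
            nets[c] = build_network(gs.name, c, nodes, pairs)
        remod = {
            case: remodeling_report(nets[config.reference], nets[case])
            for case in config.contrasts
        }
        psrs = {case: psr(set(nodes), _records(regs[case])) for case in config.contrasts}
        tds = {
            case: pathway_td_summary(set(nodes), trajs[case])
            for case in config.contrasts
            if not trajs[case].empty
        }
        quant = {
            case: summarize_quantifiers(set(nodes), regs[case], trajs[case])
            for case in config.contrasts
        }
        set_results.append(
            {
                "gene_set": gs, "nodes": nodes, "networks": nets,
                "coord": coords, "remodeling": remod, "psr": psrs,
                "pathway_td": tds, "quantifiers": quant,
            }
        )
    return {
        "table": table,
        "profiles": profiles,
        "fabric": fabric,
        "cor": cors,
        "regulation": regs,
        "trajectory": trajs,
        "gene_sets": set_results,
    }


def _records(reg_df: pd.DataFrame):
    from .regulation import RegulationRecord

    return [
        RegulationRecord(
            gene=r.gene, reference=r.reference, case=r.case,
            ave_ref=r.ave_ref, ave_case=r.ave_case, x=r.x, p=r.p,
            cut=r.cut, significant=bool(r.significant), wir=r.wir,
        )
        for r in reg_df.itertuples()
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write TSV outputs plus a manifest.

    Returns the manifest dict.  Outputs are deterministic for a fixed
    config and input files: rerunning reproduces them bit-identically.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = read_expression_table(config.expression_path, config.layout)
    gene_sets = read_gene_sets(config.gene_sets_path) if config.gene_sets_path else []
    res = _analyze(table, gene_sets, config)

    meta = {"reference": config.reference}
    written: list[str] = []

    fab = pd.concat(res["fabric"].values(), ignore_index=True)
    write_tsv(fab, outdir / "fabric_summary.tsv", meta)
    written.append("fabric_summary.tsv")

    if config.contrasts:
        reg = pd.concat(res["regulation"].values(), ignore_index=True)
        write_tsv(reg, outdir / "regulation.tsv", meta)
        traj = pd.concat(res["trajectory"].values(), ignore_index=True)
        write_tsv(traj, outdir / "trajectory.tsv", meta)
        written += ["regulation.tsv", "trajectory.tsv"]

    if res["gene_sets"]:
        coord_rows, edge_frames, remod_rows, psr_rows, td_rows = [], [], [], [], []
        for sr in res["gene_sets"]:
            name = sr["gene_set"].name
            for c, cs in sr["coord"].items():
                coord_rows.append(
                    {"gene_set": name, "condition": c, "syn_pct": cs.syn_pct,
                     "ant_pct": cs.ant_pct, "ind_pct": cs.ind_pct,
                     "coord": cs.coord, "n_pairs": cs.n_pairs}
                )
            for c, net in sr["networks"].items():
                et = network_edge_table(net)
                et.insert(0, "gene_set", name)
                edge_frames.append(et)
            for case, rep in sr["remodeling"].items():
                for klass in rep.counts_ref:
                    remod_rows.append(
                        {"gene_set": name, "reference": rep.reference, "case": case,
                         "class": klass, "n_ref": rep.counts_ref[klass],
                         "n_case": rep.counts_case[klass],
                         "pct_ref": rep.pct_ref(klass), "pct_case": rep.pct_case(klass),
                         "n_pairs": rep.n_pairs}
                    )
            for case, p in sr["psr"].items():
                psr_rows.append({"gene_set": name, "case": case, **p})
            for case, t in sr["pathway_td"].items():
                td_rows.append(
                    {"gene_set": name, "case": case, "mean_td": t["mean_td"],
                     "n_genes": t["n"]}
                )
        write_tsv(pd.DataFrame(coord_rows), outdir / "coord_scores.tsv", meta)
        write_tsv(pd.concat(edge_frames, ignore_index=True), outdir / "networks.tsv", meta)
        write_tsv(pd.DataFrame(remod_rows), outdir / "remodeling_report.tsv", meta)
        write_tsv(pd.DataFrame(psr_rows), outdir / "psr.tsv", meta)
        write_tsv(pd.DataFrame(td_rows), outdir / "pathway_td.tsv", meta)
        written += ["coord_scores.tsv", "networks.tsv", "remodeling_report.tsv",
                    "psr.tsv", "pathway_td.tsv"]

    cfg = asdict(config)
    manifest = {
        "genefabric_version": __version__,
        "config": cfg,
        "inputs": {
            "expression": file_sha256(config.expression_path),
            **(
                {"gene_sets": file_sha256(config.gene_sets_path)}
                if config.gene_sets_path
                else {}
            ),
        },
        "log": dict(res["table"].log),
        "outputs": {f: file_sha256(outdir / f) for f in written},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
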