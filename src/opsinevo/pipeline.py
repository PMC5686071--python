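"""End-to-end orchestration: simulate -> annotate -> synteny -> ancestral
-> tuning -> pcm, driven by one YAML config.

Stages communicate through plain files (TSV / FASTA / Newick) so each can
be run, inspected and tested in isolation; a JSON manifest records the
config, seed and a checksum of every file read or written.  With a fixed
seed the whole run is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .ancestral_parsimony import branch_event_table, sankoff_counts
from .io_formats import (
    read_copy_number_matrix,
    read_fasta,
    read_gene_table,
    read_habitat_table,
    read_tree,
    write_copy_number_matrix,
    write_fasta,
    write_gene_table,
    write_habitat_table,
)
from .repertoire import DEFAULT_EXON_MODEL, annotate_genes, calls_to_frame, count_repertoire
from .synteny import extract_windows, reconstruct_synteny_history, serialize_state
from .tuning import (
    asr_sites,
    default_shift_table,
    fit_rate,
    join_labels,
    label_substitutions,
    predict_lws_lambda,
    select_representative,
    LWS_FIVE_SITES,
)
from . import synthetic_data as sim

STAGES = ("simulate", "annotate", "synteny", "ancestral", "tuning", "pcm")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    stages: Sequence[str] = STAGES
    # external inputs (ignored for stages the simulate stage feeds)
    tree: str | None = None
    genes: str | None = None
    cds: str | None = None
    refs: str | None = None
    habitats: str | None = None
    orders: str | None = None
    matrix: str | None = None
    shift_table: str | None = None
    # knobs
    call_threshold: float = 0.3
    search_depth: int = 4
    nmax: int | None = None
    families: Sequence[str] = ("LWS", "SWS1", "SWS2", "Rh2", "Rh1")
    pcm_family: str = "LWS"
    pcm_comparison: str = "salinity"
    # simulate stage
    n_species: int = 12
    tree_height: float = 200.0
    divergence: float = 0.03
    pseudogene_fraction: float = 0.1
    truncated_fraction: float = 0.1
    habitat_q: float = 0.004
    copy_gain_rate: float = 0.0015
    copy_loss_rate: float = 0.0015
    wgd_retention: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def validate_config(config: RunConfig) -> list[str]:
    """Pre-flight check; an empty list means run_pipeline would start."""
    issues: list[str] = []
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        issues.append(f"unknown stages: {sorted(unknown)}")
    if not 0 <= config.call_threshold <= 1:
        issues.append(f"call threshold {config.call_threshold} outside [0, 1]")
    if config.search_depth < 1:
        issues.append("search depth must be >= 1")
    if config.n_species < 3:
        issues.append("need at least 3 species")
    simulated = "simulate" in config.stages
    needs = {
        "annotate": ["genes", "cds", "refs"],
        "synteny": ["orders", "tree"],
        "ancestral": ["matrix", "tree"],
        "tuning": ["cds", "tree"],
        "pcm": ["matrix", "tree", "habitats"],
    }
    for stage in config.stages:
        for inp in needs.get(stage, []):
            if inp == "matrix" and "annotate" in config.stages:
                continue
            path = getattr(config, inp, None)
            if simulated:
                continue  # produced by the simulate stage
            if path is None:
                issues.append(f"stage {stage!r} needs input {inp!r}")
            elif not Path(path).exists():
                issues.append(f"stage {stage!r}: missing file {path}")
    return issues


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_df(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


class ConfigError(ValueError):
    """The run configuration failed pre-flight validation."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause;
    outputs written by earlier stages are kept."""


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest
    (also written to ``manifest.json``).  A stage failure aborts the run
    with the stage name, keeping prior outputs."""
    current: list = [None]
    try:
        return _execute(config, current)
    except (ConfigError, StageError):
        raise
    except Exception as exc:
        raise StageError(f"stage {current[0]!r} failed: {exc}") from exc


def _execute(config: RunConfig, current: list) -> dict:
    issues = validate_config(config)
    if issues:
        raise ConfigError("invalid config: " + "; ".join(issues))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    summary: dict[str, dict] = {}
    paths = {k: getattr(config, k) for k in
             ("tree", "genes", "cds", "refs", "habitats", "orders", "matrix")}

    def emit(name: str, path: Path) -> None:
        files[name] = _sha256(path)

    # ---- simulate ------------------------------------------------------
    if "simulate" in config.stages:
        current[0] = "simulate"
        tree = sim.simulate_tree(
            n_species=config.n_species, seed=config.seed, rescale_height=config.tree_height
        )
        # mark one internal branch (the first postorder internal non-root
        # node) as a WGD, standing in for a lineage-specific 4R
        internals = [n for n in tree.node_ids("postorder")
                     if not tree.node(n).is_leaf() and n != tree.root_id]
        if internals:
            tree.wgd_branches[internals[0]] = "4R"
        tree.write(out / "tree.nwk")
        paths["tree"] = out / "tree.nwk"

        refs = sim.make_family_references(config.families, seed=config.seed)
        write_fasta({f"{k}_ref": v for k, v in refs.items()}, out / "refs.fa")
        paths["refs"] = out / "refs.fa"

        cds_set = sim.simulate_cds_set(
            species=tree.leaf_labels,
            references=refs,
            divergence=config.divergence,
            pseudogene_fraction=config.pseudogene_fraction,
            truncated_fraction=config.truncated_fraction,
            substitutions={"Rh2": [(122, "E", "Q")]},
            expected_exons=DEFAULT_EXON_MODEL,
            seed=config.seed,
        )
        write_gene_table(cds_set.gene_table, out / "genes.tsv")
        write_fasta(cds_set.cds, out / "cds.fa")
        paths["genes"], paths["cds"] = out / "genes.tsv", out / "cds.fa"
        truth = pd.DataFrame(
            [
                {"gene_id": g, "status": cds_set.truth_status[g],
                 "family": cds_set.truth_family[g]}
                for g in sorted(cds_set.truth_status)
            ]
        )
        _write_df(truth, out / "truth_status.tsv")

        habitat, _ = sim.simulate_habitats(tree, q=config.habitat_q, seed=config.seed)
        write_habitat_table(habitat, out / "habitats.tsv")
        paths["habitats"] = out / "habitats.tsv"

        orders = sim.simulate_gene_orders(
            tree,
            loss_rate=0.002,
            dup_rate=0.001,
            inversion_rate=0.001,
            translocation_rate=0.0005,
            seed=config.seed,
        )
        rows = []
        for sp in sorted(orders.orders):
            for contig_i, contig in enumerate(sim.orders_to_contigs(orders.orders[sp])):
                for pos, (name, orient, is_ops) in enumerate(contig):
                    rows.append(
                        {
                            "species": sp,
                            "contig": f"{sp}_c{contig_i + 1}",
                            "position": pos,
                            "gene": name,
                            "orient": "+" if orient >= 0 else "-",
                            "is_opsin": int(is_ops),
                        }
                    )
        _write_df(pd.DataFrame(rows), out / "orders.tsv")
        paths["orders"] = out / "orders.tsv"
        for name in ("tree.nwk", "refs.fa", "genes.tsv", "cds.fa",
                     "truth_status.tsv", "habitats.tsv", "orders.tsv"):
            emit(name, out / name)
        summary["simulate"] = {
            "n_species": config.n_species,
            "n_genes": len(cds_set.gene_table),
            "wgd_branches": dict(tree.wgd_branches),
        }

    tree = read_tree(paths["tree"]) if paths.get("tree") else None

    # ---- annotate ------------------------------------------------------
    if "annotate" in config.stages:
        current[0] = "annotate"
        records = read_gene_table(paths["genes"])
        cds = read_fasta(paths["cds"])
        for r in records:
            if not r.cds and r.gene_id in cds:
                r.cds = cds[r.gene_id]
        refs = read_fasta(paths["refs"])
        calls = annotate_genes(records, refs, call_threshold=config.call_threshold)
        frame = calls_to_frame(calls)
        _write_df(frame, out / "calls.tsv")
        counts = count_repertoire(
            calls, species=tree.leaf_labels if tree else None, families=config.families
        )
        write_copy_number_matrix(counts, out / "counts.tsv")
        paths["matrix"] = out / "counts.tsv"
        emit("calls.tsv", out / "calls.tsv")
        emit("counts.tsv", out / "counts.tsv")
        summary["annotate"] = {
            "n_genes": len(calls),
            "by_status": frame["status"].value_counts().to_dict(),
        }

    # ---- synteny -------------------------------------------------------
    if "synteny" in config.stages:
        current[0] = "synteny"
        odf = pd.read_csv(paths["orders"], sep="\t")
        leaf_blocks: dict[str, list] = {}
        for (sp, contig), grp in odf.groupby(["species", "contig"]):
            grp = grp.sort_values("position")
            order = [
                (row["gene"], 1 if row["orient"] == "+" else -1, bool(row["is_opsin"]))
                for _, row in grp.iterrows()
            ]
            leaf_blocks.setdefault(sp, []).extend(
                extract_windows(order, species=sp, contig=str(contig))
            )
        history = reconstruct_synteny_history(tree, leaf_blocks, max_depth=config.search_depth)
        ev_rows = [
            {"branch": e.branch, "event_type": e.event, "payload": e.payload}
            for e in history.events
        ]
        _write_df(pd.DataFrame(ev_rows, columns=["branch", "event_type", "payload"]),
                  out / "synteny_events.tsv")
        node_rows = [
            {"node": nid, "blocks": serialize_state(state)}
            for nid, state in sorted(history.node_states.items())
        ]
        _write_df(pd.DataFrame(node_rows, columns=["node", "blocks"]),
                  out / "synteny_nodes.tsv")
        emit("synteny_events.tsv", out / "synteny_events.tsv")
        emit("synteny_nodes.tsv", out / "synteny_nodes.tsv")
        summary["synteny"] = {
            "total_events": len(history.events),
            "unresolved_branches": history.unresolved,
        }

    # ---- ancestral copy numbers ---------------------------------------
    if "ancestral" in config.stages:
        current[0] = "ancestral"
        matrix = read_copy_number_matrix(paths["matrix"])
        node_rows, event_rows = [], []
        for fam in matrix.columns:
            leaf_counts = {sp: int(matrix.loc[sp, fam]) for sp in matrix.index
                           if sp in set(tree.leaf_labels)}
            res = sankoff_counts(tree, leaf_counts, nmax=config.nmax, family=fam)
            for nid in tree.node_ids("preorder"):
                node_rows.append(
                    {
                        "family": fam,
                        "node": nid,
                        "count": res.node_count[nid],
                        "ambiguous": ",".join(map(str, sorted(res.ambiguity[nid]))),
                    }
                )
            for ev in branch_event_table(tree, res):
                event_rows.append(
                    {"family": fam, "branch": ev.branch, "event": ev.event,
                     "magnitude": ev.magnitude}
                )
        _write_df(pd.DataFrame(node_rows), out / "anc_counts.tsv")
        _write_df(pd.DataFrame(event_rows, columns=["family", "branch", "event", "magnitude"]),
                  out / "anc_events.tsv")
        emit("anc_counts.tsv", out / "anc_counts.tsv")
        emit("anc_events.tsv", out / "anc_events.tsv")
        summary["ancestral"] = {"n_events": len(event_rows)}

    # ---- tuning --------------------------------------------------------
    if "tuning" in config.stages:
        current[0] = "tuning"
        refs = read_fasta(paths["refs"])
        cds = read_fasta(paths["cds"])
        calls_df = pd.read_csv(out / "calls.tsv", sep="\t") if (out / "calls.tsv").exists() else None
        table = default_shift_table()
        from Bio.Seq import Seq

        site_rows, sub_rows, lambda_rows = [], [], []
        for fam in config.families:
            ref_id = f"{fam}_ref" if f"{fam}_ref" in refs else fam
            if ref_id not in refs:
                continue
            fam_ref = refs[ref_id]
            # species representatives: complete genes of this family
            per_species: dict[str, dict[str, str]] = {}
            if calls_df is not None:
                sel = calls_df[(calls_df["family"] == fam) & (calls_df["status"] == "complete")]
                for _, row in sel.iterrows():
                    prot = str(Seq(cds[row["gene_id"]]).translate()).rstrip("*")
                    per_species.setdefault(row["species"], {})[row["gene_id"]] = prot
            residues: dict[str, dict[int, str]] = {}
            fam_alias = {"Exorh": "Rh1"}.get(fam, fam)
            fam_sites = sorted(
                set(table.df[table.df["family"] == fam_alias]["site"].astype(int))
            )
            for sp, cands in per_species.items():
                rep = select_representative(cands, fam_ref)
                prot = cands[rep]
                res = {}
                for site in fam_sites:
                    if site <= len(prot):
                        res[site] = prot[site - 1]
                residues[sp] = res
                for site, r in res.items():
                    site_rows.append(
                        {"family": fam, "species": sp, "gene_id": rep,
                         "site": site, "residue": r}
                    )
            # ancestral reconstruction on sites variable across species
            leaves_with = [sp for sp in tree.leaf_labels if sp in residues]
            if len(leaves_with) == len(tree.leaf_labels) and leaves_with:
                columns = {
                    site: {sp: residues[sp].get(site, "X") for sp in leaves_with}
                    for site in fam_sites
                }
                variable = {
                    s: col for s, col in columns.items() if len(set(col.values())) > 1
                }
                if variable:
                    rate = fit_rate(tree, variable)
                    states = {
                        s: asr_sites(tree, col, site=s, rate=rate)
                        for s, col in variable.items()
                    }
                    labels = label_substitutions(states, tree)
                    for branch in sorted(labels):
                        sub_rows.append(
                            {"family": fam, "branch": branch,
                             "labels": join_labels(labels[branch])}
                        )
            if fam == "LWS":
                for sp in sorted(residues):
                    geno = {s: residues[sp].get(s, "?") for s in LWS_FIVE_SITES}
                    try:
                        lam = predict_lws_lambda(geno, table)
                        lam_txt = f"{lam:.1f}"
                    except (KeyError, ValueError):
                        lam_txt = "NA"
                    lambda_rows.append(
                        {"species": sp,
                         "genotype": "".join(geno[s] for s in LWS_FIVE_SITES),
                         "lambda_max_nm": lam_txt}
                    )
        _write_df(pd.DataFrame(site_rows, columns=["family", "species", "gene_id", "site", "residue"]),
                  out / "sites.tsv")
        _write_df(pd.DataFrame(sub_rows, columns=["family", "branch", "labels"]),
                  out / "branch_subs.tsv")
        _write_df(pd.DataFrame(lambda_rows, columns=["species", "genotype", "lambda_max_nm"]),
                  out / "lambda.tsv")
        for name in ("sites.tsv", "branch_subs.tsv", "lambda.tsv"):
            emit(name, out / name)
        summary["tuning"] = {"n_branch_substitutions": len(sub_rows)}

    # ---- pcm -----------------------------------------------------------
    if "pcm" in config.stages:
        current[0] = "pcm"
        from .pcm import run_comparison

        matrix = read_copy_number_matrix(paths["matrix"])
        habitats = read_habitat_table(paths["habitats"])
        states = habitats.states_for(config.pcm_comparison)
        counts = {sp: float(matrix.loc[sp, config.pcm_family]) for sp in matrix.index}
        fits, report = run_comparison(tree, counts, states)
        rows = []
        for m, f in fits.items():
            rows.append(
                {
                    "model": m,
                    "k": f.k,
                    "logL": round(f.logL, 6),
                    "AIC": round(f.aic, 6),
                    "BIC": round(f.bic, 6),
                    "params": json.dumps({k: round(v, 6) for k, v in f.params.items()},
                                         sort_keys=True),
                }
            )
        _write_df(pd.DataFrame(rows), out / "pcm_report.tsv")
        comp_rows = [
            {k: (round(v, 6) if isinstance(v, float) else v) for k, v in r.items()}
            for r in report.as_rows()
        ]
        _write_df(pd.DataFrame(comp_rows), out / "pcm_tests.tsv")
        emit("pcm_report.tsv", out / "pcm_report.tsv")
        emit("pcm_tests.tsv", out / "pcm_tests.tsv")
        summary["pcm"] = {
            "family": config.pcm_family,
            "comparison": config.pcm_comparison,
            "significant_difference": bool(report.significant_difference),
        }

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "files": dict(sorted(files.items())),
        "summary": summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
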