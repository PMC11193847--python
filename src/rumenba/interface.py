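"""Table IO, pipeline orchestration, and the command-line interface.

Dialects
--------
* MAG catalog TSV: ``mag_id  completeness  contamination  taxonomy`` with a
  semicolon-delimited GTDB-style taxonomy string (``d__...;...;s__...``).
* KO annotation TSV: ``gene_id  mag_id  ko_id`` (KofamScan-like, pre-filtered;
  an extra score column is ignored with a log note).
* Isolate TSV: ``organism_id  ko_id``.
* Name-map TSV: ``gtdb_name  ncbi_name``.
* Concentration CSV: first column sample id, second column group, remaining
  columns bile-acid names; values nmol/L; missing token ``NA``.

All files are UTF-8 (bile-acid names use Greek letters).  Every output file
starts with a provenance header line recording tool version, config hash and
seed.  Outputs are never overwritten without ``force``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__
from .baquant import (ConcentrationMatrix, DifferentialConfig,
                      EXOGENOUS_BAS, differential_bas, pool_totals,
                      transformed_fraction)
from .bagraph import (RUMEN_PATHWAY_EDGES, STRUCTURES, enumerate_edges,
                      validate_pathway)
from .banet import build_network, hub_nodes, spearman_matrix
from .magscreen import (DEFAULT_BAKO_CATALOG, MagRecord, filter_mags,
                        screen_bakos, summarize_proportions,
                        taxonomy_breakdown)
from .mediate import MediationInput, bootstrap_mediation, sensitivity_curve
from .synthdata import SynthConfig, gen_ba_matrix, gen_mag_catalog, \
    gen_mediation_data

log = logging.getLogger(__name__)

NA_TOKEN = "NA"

# Exit codes: 0 ok, 1 usage, 2 data error, 3 invariant violation.
EXIT_OK, EXIT_USAGE, EXIT_DATA, EXIT_INVARIANT = 0, 1, 2, 3


# ---------------------------------------------------------------------------
# Readers / writers


def _provenance_header(seed: int | None, config_hash: str) -> str:
    return (f"# rumenba {__version__} config={config_hash} "
            f"seed={'NA' if seed is None else seed}\n")


def _write_table(df: pd.DataFrame, path: Path, sep: str, seed: int | None,
                 config_hash: str, force: bool, index: bool = False) -> None:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_provenance_header(seed, config_hash))
        df.to_csv(fh, sep=sep, index=index, na_rep=NA_TOKEN)


def _read_table(path: Path, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", encoding="utf-8",
                       na_values=[NA_TOKEN], keep_default_na=False,
                       float_precision="round_trip")


def write_mag_tables(mag_table: pd.DataFrame, ko_table: pd.DataFrame,
                     mag_path, ko_path, seed: int | None = None,
                     config_hash: str = "-", force: bool = False) -> None:
    _write_table(mag_table, Path(mag_path), "\t", seed, config_hash, force)
    _write_table(ko_table, Path(ko_path), "\t", seed, config_hash, force)


def read_mag_catalog(mag_path, ko_path) -> list[MagRecord]:
    """Load MAG + KO annotation TSVs into MagRecord objects."""
    mags = _read_table(Path(mag_path), "\t")
    required = {"mag_id", "completeness", "contamination", "taxonomy"}
    if not required <= set(mags.columns):
        raise ValueError(f"MAG table needs columns {sorted(required)}")
    kos = _read_table(Path(ko_path), "\t")
    if not {"gene_id", "mag_id", "ko_id"} <= set(kos.columns):
        raise ValueError("KO table needs columns gene_id, mag_id, ko_id")
    extra = set(kos.columns) - {"gene_id", "mag_id", "ko_id"}
    if extra:
        log.info("KO table: ignoring extra column(s) %s (assumed pre-filtered "
                 "score output)", sorted(extra))
    counts = kos.groupby(["mag_id", "ko_id"]).size()
    by_mag: dict[str, dict[str, int]] = {}
    for (mag_id, ko_id), n in counts.items():
        by_mag.setdefault(str(mag_id), {})[str(ko_id)] = int(n)
    records = []
    for row in mags.itertuples(index=False):
        gene_counts = by_mag.get(str(row.mag_id), {})
        records.append(MagRecord(
            mag_id=str(row.mag_id),
            completeness=float(row.completeness),
            contamination=float(row.contamination),
            taxonomy="" if pd.isna(row.taxonomy) else str(row.taxonomy),
            ko_set=frozenset(gene_counts),
            gene_count_per_ko=gene_counts,
        ))
    return records


def write_concentrations(matrix: ConcentrationMatrix, path,
                         seed: int | None = None, config_hash: str = "-",
                         force: bool = False) -> None:
    df = matrix.values.copy()
    df.insert(0, "group", matrix.groups)
    df.insert(0, "sample_id", matrix.values.index)
    _write_table(df, Path(path), ",", seed, config_hash, force)


def read_concentrations(path) -> ConcentrationMatrix:
    df = _read_table(Path(path), ",")
    if df.shape[1] < 3:
        raise ValueError("concentration CSV needs sample id, group, and at "
                         "least one bile-acid column")
    sample_col, group_col = df.columns[:2]
    values = df.set_index(sample_col).drop(columns=[group_col]).astype(float)
    groups = df.set_index(sample_col)[group_col].astype(str)
    return ConcentrationMatrix(values=values, groups=groups)


def read_name_list(path) -> list[str]:
    """Plain-text differential-feature list, one name per line."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_name_map(path) -> dict[str, str]:
    df = _read_table(Path(path), "\t")
    if not {"gtdb_name", "ncbi_name"} <= set(df.columns):
        raise ValueError("name map needs columns gtdb_name, ncbi_name")
    return dict(zip(df["gtdb_name"].astype(str), df["ncbi_name"].astype(str)))


def write_edge_list(graph, path, seed: int | None = None,
                    config_hash: str = "-", force: bool = False) -> None:
    rows = [{"substrate": s, "product": p, "reaction": op.reaction,
             "position": op.position,
             "orientation": op.target_orientation or NA_TOKEN}
            for s, p, op in graph.edges]
    _write_table(pd.DataFrame(rows), Path(path), "\t", seed, config_hash, force)


def write_network(network, path, seed: int | None = None,
                  config_hash: str = "-", force: bool = False) -> None:
    rows = [{"node_a": u, "node_b": v, "r": d.get("r"), "p": d.get("p"),
             "p_adj": d.get("p_adj"), "rule": network.rule}
            for u, v, d in network.edges]
    _write_table(pd.DataFrame(rows), Path(path), "\t", seed, config_hash, force)


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineConfig:
    """Inputs, parameters and output location for an end-to-end run."""

    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = ("screen", "quant", "graph", "network", "mediate")
    synth: SynthConfig | None = None        # generate inputs when set
    mag_path: Path | None = None
    ko_path: Path | None = None
    conc_path: Path | None = None
    groups: tuple[str, str] = ("control", "treated")
    min_completeness: float = 80.0
    max_contamination: float = 10.0
    alpha: float = 0.05
    vip_threshold: float = 1.0
    test: str = "student_t"
    network_rule: str = "exact_unit"
    bootstrap_sims: int = 1000
    force: bool = False
    extra: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in self.__dict__.items()
                   if k not in ("outdir", "force")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


_STAGE_ORDER = ("simulate", "screen", "quant", "graph", "network", "mediate")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages in dependency order.

    Returns a machine-readable status bundle; a stage failure stops its
    dependants and is recorded rather than raised.
    """
    unknown = set(config.stages) - set(_STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seed = config.seed
    status: dict = {"version": __version__, "config_hash": chash,
                    "seed": seed, "stages": {}}

    synth = config.synth.with_seed(seed) if config.synth else None

    # Pre-flight: every requested stage must have its inputs.
    gaps = []
    if "screen" in config.stages and synth is None and \
            (config.mag_path is None or config.ko_path is None):
        gaps.append("screen: MAG/KO tables or a synthetic config required")
    if "quant" in config.stages and synth is None and config.conc_path is None:
        gaps.append("quant: concentration CSV or a synthetic config required")
    if gaps:
        raise FileNotFoundError("missing inputs: " + "; ".join(gaps))

    def record(stage, ok, **info):
        status["stages"][stage] = {"ok": ok, **info}

    matrix = None
    try:
        if synth is not None:
            mag_table, ko_table = gen_mag_catalog(synth)
            write_mag_tables(mag_table, ko_table, outdir / "mags.tsv",
                             outdir / "kos.tsv", seed, chash, config.force)
            matrix = gen_ba_matrix(synth)
            write_concentrations(matrix, outdir / "concentrations.csv",
                                 seed, chash, config.force)
            catalog = read_mag_catalog(outdir / "mags.tsv", outdir / "kos.tsv")
            record("simulate", True, n_mags=len(catalog))
        elif config.mag_path is not None:
            catalog = read_mag_catalog(config.mag_path, config.ko_path)
        else:
            catalog = None
        if matrix is None and config.conc_path is not None:
            matrix = read_concentrations(config.conc_path)
    except Exception as exc:   # input failure poisons everything downstream
        record("simulate", False, error=str(exc))
        return status

    if "screen" in config.stages:
        try:
            kept = filter_mags(catalog, config.min_completeness,
                               config.max_contamination)
            summary = screen_bakos(kept, DEFAULT_BAKO_CATALOG)
            props = summarize_proportions(summary)
            _write_table(props, outdir / "bako_proportions.tsv", "\t", seed,
                         chash, config.force)
            bamags = [r for r in kept if r.mag_id in summary.bamag_ids]
            fam = taxonomy_breakdown(bamags, "family")
            (outdir / "family_breakdown.json").write_text(
                json.dumps(fam, ensure_ascii=False, indent=1), encoding="utf-8")
            record("screen", True, n_filtered=len(kept),
                   n_bamags=summary.n_bamags)
        except Exception as exc:
            record("screen", False, error=str(exc))

    diff = None
    if "quant" in config.stages:
        try:
            totals = pool_totals(matrix)
            _write_table(totals.reset_index(names="sample_id"),
                         outdir / "pool_totals.tsv", "\t", seed, chash,
                         config.force)
            diff = differential_bas(
                matrix, config.groups,
                DifferentialConfig(test=config.test, alpha=config.alpha,
                                   vip_threshold=config.vip_threshold))
            _write_table(diff, outdir / "differential_bas.tsv", "\t", seed,
                         chash, config.force)
            treated_means = matrix.group_values(config.groups[1]).mean()
            frac = transformed_fraction(treated_means, EXOGENOUS_BAS)
            record("quant", True, transformed_fraction=frac,
                   n_significant=int(diff["significant"].sum()))
        except Exception as exc:
            record("quant", False, error=str(exc))

    if "graph" in config.stages:
        try:
            graph = enumerate_edges(STRUCTURES.values(), mode="both")
            write_edge_list(graph, outdir / "biotransformation_edges.tsv",
                            seed, chash, config.force)
            report = validate_pathway(
                graph, [(s, p) for s, p, _ in RUMEN_PATHWAY_EDGES])
            record("graph", True, n_edges=len(graph.edges),
                   pathway_found=len(report["found"]),
                   pathway_missing=len(report["missing"]))
        except Exception as exc:
            record("graph", False, error=str(exc))

    if "network" in config.stages:
        try:
            if diff is not None and diff["significant"].any():
                cols = diff.loc[diff["significant"], "name"].tolist()
            else:
                cols = matrix.bas
            treated = matrix.group_values(config.groups[1])[cols]
            r, p = spearman_matrix(treated)
            net = build_network(r, p, rule=config.network_rule,
                                alpha=config.alpha)
            write_network(net, outdir / "correlation_network.tsv", seed,
                          chash, config.force)
            hubs = hub_nodes(net, k=3)
            record("network", True, n_edges=net.graph.number_of_edges(),
                   hubs=hubs)
        except Exception as exc:
            record("network", False, error=str(exc))

    if "mediate" in config.stages:
        try:
            med_cfg = synth if synth is not None else SynthConfig(seed=seed)
            data = gen_mediation_data(med_cfg)
            X = MediationInput(data["treatment"], data["mediator"],
                               data["outcome"])
            fit = bootstrap_mediation(X, sims=config.bootstrap_sims, seed=seed)
            sens = sensitivity_curve(X)
            result = {
                "acme": fit.acme, "ade": fit.ade, "total": fit.total,
                "prop_mediated": fit.prop_mediated,
                "ci_acme": fit.ci["acme"], "p_mediation": fit.p_mediation,
                "sims": fit.sims, "rho_zero": sens.rho_zero,
                "truth": data["truth"],
            }
            (outdir / "mediation.json").write_text(
                json.dumps(result, indent=1), encoding="utf-8")
            record("mediate", True, acme=fit.acme,
                   p_mediation=fit.p_mediation)
        except Exception as exc:
            record("mediate", False, error=str(exc))

    (outdir / "status.json").write_text(json.dumps(status, indent=1),
                                        encoding="utf-8")
    return status


# ---------------------------------------------------------------------------
# CLI


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="debug logging")
def main(verbose: bool) -> None:
    """Rumen bile-acid microbiome analysis pipeline."""
    logging.basicConfig(stream=sys.stderr,
                        level=logging.DEBUG if verbose else logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")


def _common(outdir, seed, force, stages) -> PipelineConfig:
    return PipelineConfig(outdir=Path(outdir), seed=seed, force=force,
                          stages=stages, synth=SynthConfig(seed=seed))


def _run(config: PipelineConfig) -> None:
    try:
        status = run_pipeline(config)
    except FileNotFoundError as exc:
        click.echo(f"error: {exc}", err=True)
        raise SystemExit(EXIT_DATA)
    except ValueError as exc:
        click.echo(f"error: {exc}", err=True)
        raise SystemExit(EXIT_USAGE)
    failed = [s for s, st in status["stages"].items() if not st["ok"]]
    click.echo(json.dumps(status, indent=1))
    raise SystemExit(EXIT_INVARIANT if failed else EXIT_OK)


@main.command()
@click.option("--outdir", required=True, type=click.Path())
@click.option("--seed", default=0, show_default=True)
@click.option("--n-mags", default=5000, show_default=True)
@click.option("--force", is_flag=True)
def simulate(outdir, seed, n_mags, force):
    """Generate synthetic MAG, KO and concentration tables."""
    cfg = PipelineConfig(outdir=Path(outdir), seed=seed, force=force,
                         stages=(),
                         synth=SynthConfig(seed=seed, n_mags=n_mags))
    cfg.stages = ("simulate",)
    _run(cfg)


@main.command()
@click.option("--mags", "mag_path", required=True, type=click.Path(exists=True))
@click.option("--kos", "ko_path", required=True, type=click.Path(exists=True))
@click.option("--outdir", required=True, type=click.Path())
@click.option("--min-completeness", default=80.0, show_default=True)
@click.option("--max-contamination", default=10.0, show_default=True)
@click.option("--force", is_flag=True)
def screen(mag_path, ko_path, outdir, min_completeness, max_contamination,
           force):
    """Filter MAGs and screen for bile-acid KEGG orthologs."""
    _run(PipelineConfig(outdir=Path(outdir), stages=("screen",),
                        mag_path=Path(mag_path), ko_path=Path(ko_path),
                        min_completeness=min_completeness,
                        max_contamination=max_contamination, force=force))


@main.command()
@click.option("--concentrations", "conc_path", required=True,
              type=click.Path(exists=True))
@click.option("--outdir", required=True, type=click.Path())
@click.option("--groups", nargs=2, default=("control", "treated"),
              show_default=True)
@click.option("--test", default="student_t", show_default=True,
              type=click.Choice(["student_t", "wilcoxon"]))
@click.option("--alpha", default=0.05, show_default=True)
@click.option("--force", is_flag=True)
def quant(conc_path, outdir, groups, test, alpha, force):
    """Pool totals, transformed fraction and differential bile acids."""
    _run(PipelineConfig(outdir=Path(outdir), stages=("quant",),
                        conc_path=Path(conc_path), groups=tuple(groups),
                        test=test, alpha=alpha, force=force))


@main.command()
@click.option("--outdir", required=True, type=click.Path())
@click.option("--force", is_flag=True)
def graph(outdir, force):
    """Enumerate the bile-acid biotransformation graph."""
    _run(PipelineConfig(outdir=Path(outdir), stages=("graph",), force=force))


@main.command()
@click.option("--concentrations", "conc_path", required=True,
              type=click.Path(exists=True))
@click.option("--outdir", required=True, type=click.Path())
@click.option("--rule", default="exact_unit", show_default=True,
              type=click.Choice(["exact_unit", "bh_alpha"]))
@click.option("--groups", nargs=2, default=("control", "treated"),
              show_default=True)
@click.option("--force", is_flag=True)
def network(conc_path, outdir, rule, groups, force):
    """Spearman correlation network over the treated group."""
    _run(PipelineConfig(outdir=Path(outdir), stages=("network",),
                        conc_path=Path(conc_path), network_rule=rule,
                        groups=tuple(groups), force=force))


@main.command()
@click.option("--outdir", required=True, type=click.Path())
@click.option("--seed", default=0, show_default=True)
@click.option("--sims", default=1000, show_default=True)
@click.option("--force", is_flag=True)
def mediate(outdir, seed, sims, force):
    """Bootstrap mediation analysis on a synthetic triad."""
    cfg = _common(outdir, seed, force, ("mediate",))
    cfg.bootstrap_sims = sims
    _run(cfg)


@main.command(name="run-all")
@click.option("--outdir", required=True, type=click.Path())
@click.option("--seed", default=0, show_default=True)
@click.option("--force", is_flag=True)
def run_all(outdir, seed, force):
    """Full synthetic pipeline: simulate, screen, quant, graph, network,
    mediation."""
    _run(_common(outdir, seed, force,
                 ("simulate", "screen", "quant", "graph", "network",
                  "mediate")))


if __name__ == "__main__":
    main()
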