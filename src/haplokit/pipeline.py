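"""Full-analysis orchestration: one config in, a report bundle out.

The bundle mirrors the standard presentation of a targeted-locus survey:
a variant table (site, position, type, alleles, consequence, per-population
carrier counts), a diversity table (n, S, h, Hd, π), pairwise + overall
Hudson FST, neutrality statistics, rarefaction per-replicate TSVs and a
summary JSON, network exports, and a run manifest. Output is bit-stable for
a fixed seed; floats are printed at fixed precision (Hd 3 dp, π 5 dp,
FST 4 dp).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

from . import __version__
from .alignment import Alignment, label_populations, read_fasta, read_popmap
from .diversity import (
    diversity_summary,
    hudson_fst_overall,
    hudson_fst_pairwise,
    neutrality_summary,
)
from .network import build_mjn, export_network, write_node_table
from .rarefaction import RarefactionConfig, rarefy_population
from .simulate import anafp_fixture
from .variants import (
    assign_haplotypes,
    carrier_counts,
    classify_coding_consequence,
    detect_variable_sites,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str | Path = "haplokit_out"
    alignment: str | Path | None = None
    popmap: str | Path | None = None
    fixture: bool = False
    subsample_size: int = 16
    replicates: int = 1000
    seed: int = 0
    populations: tuple[str, ...] | None = None  # rarefaction targets
    epsilon: int = 0

    def __post_init__(self) -> None:
        if self.fixture == (self.alignment is not None and self.popmap is not None):
            raise ValueError(
                "provide either --fixture or both an alignment and a popmap"
            )
        if self.subsample_size < 2 or self.replicates < 1:
            raise ValueError("subsample size must be >= 2 and replicates >= 1")


def _load(cfg: RunConfig) -> Alignment:
    if cfg.fixture:
        aln, popmap = anafp_fixture()
        return aln
    aln = read_fasta(cfg.alignment)
    return label_populations(aln, read_popmap(cfg.popmap))


def _fmt(value: float | None, nd: int) -> str:
    return "NA" if value is None else f"{value:.{nd}f}"


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every analysis stage and write the report bundle to
    ``cfg.out_dir``; returns the in-memory results. Partially written
    outputs are removed if any stage fails."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(cfg, out, written)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _run(cfg: RunConfig, out: Path, written: list[Path]) -> dict:
    aln = _load(cfg)
    pops = aln.populations()
    sizes = aln.population_sizes()
    logger.info("loaded %d records, %d columns, populations %s",
                len(aln), aln.length, sizes)

    sites = detect_variable_sites(aln)
    table = assign_haplotypes(aln, sites)

    # --- variant table -----------------------------------------------------
    path = out / "variants.tsv"
    written.append(path)
    with open(path, "w") as fh:
        fh.write("# coding consequences are reference-based in silico "
                 "annotations; the majority state stands in as reference\n")
        fh.write("site_id\tposition\tvtype\tref_state\tvar_state\tconsequence"
                 + "".join(f"\t{p}" for p in pops) + "\n")
        for i, site in enumerate(sites, start=1):
            for var_state in site.var_states:
                consequence = classify_coding_consequence(site, indel_span=1)
                carriers = carrier_counts(table, site, var_state)
                fh.write(
                    f"Var{i}\t{site.position_1based}\t{site.vtype.value}\t"
                    f"{site.ref_state}\t{var_state}\t{consequence.value}"
                    + "".join(f"\t{carriers[p]}" for p in pops) + "\n"
                )

    # --- diversity table ---------------------------------------------------
    summaries = {p: diversity_summary(aln, p) for p in pops}
    path = out / "diversity.tsv"
    written.append(path)
    with open(path, "w") as fh:
        fh.write("population\tn\tS\th\tHd\tpi\tmean_pairwise_diff\tL\n")
        for p in pops:
            s = summaries[p]
            fh.write(
                f"{p}\t{s.n}\t{s.S}\t{s.h}\t{_fmt(s.Hd, 3)}\t{_fmt(s.pi, 5)}\t"
                f"{s.mean_pairwise_diff:.6f}\t{s.L}\n"
            )

    # --- FST ---------------------------------------------------------------
    fst_results = [hudson_fst_pairwise(aln, a, b) for a, b in combinations(pops, 2)]
    if len(pops) >= 2:
        fst_results.append(hudson_fst_overall(aln, pops))
    path = out / "fst.tsv"
    written.append(path)
    with open(path, "w") as fh:
        fh.write("comparison\tfst\tHw\tHb\tdegenerate\n")
        for res in fst_results:
            name = (
                " vs ".join(res.comparison)
                if len(res.comparison) == 2
                else "overall (" + ", ".join(res.comparison) + ")"
            )
            fh.write(
                f"{name}\t{_fmt(res.fst, 4)}\t{res.Hw:.6f}\t{res.Hb:.6f}\t"
                f"{str(res.degenerate).lower()}\n"
            )

    # --- neutrality --------------------------------------------------------
    neutrality = {p: neutrality_summary(aln, p) for p in pops if sizes[p] >= 4}
    path = out / "neutrality.tsv"
    written.append(path)
    with open(path, "w") as fh:
        fh.write("population\tn\tS\teta\teta_singletons\ttajima_D\t"
                 "fu_li_D_star\tfu_li_F_star\n")
        for p in pops:
            if p not in neutrality:
                continue
            r = neutrality[p]
            fh.write(
                f"{p}\t{r.n}\t{r.S}\t{r.eta}\t{r.eta_singletons}\t"
                f"{_fmt(r.tajima_d, 3)}\t{_fmt(r.fu_li_d_star, 3)}\t"
                f"{_fmt(r.fu_li_f_star, 3)}\n"
            )

    # --- rarefaction -------------------------------------------------------
    targets = cfg.populations if cfg.populations else tuple(pops)
    too_small = [p for p in targets if sizes[p] < cfg.subsample_size]
    if too_small:
        raise ValueError(
            f"subsample size g={cfg.subsample_size} exceeds population size "
            f"of: {', '.join(f'{p} (n={sizes[p]})' for p in too_small)}"
        )
    rarefactions = {}
    for p in targets:
        summary = rarefy_population(
            aln,
            RarefactionConfig(
                population=p,
                subsample_size=cfg.subsample_size,
                replicates=cfg.replicates,
                seed=cfg.seed,
            ),
        )
        rarefactions[p] = summary
        path = out / f"rarefaction_{p}.tsv"
        written.append(path)
        with open(path, "w") as fh:
            fh.write("replicate\tS\th\n")
            for rep, (s_r, h_r) in enumerate(zip(summary.S_r, summary.h_r), 1):
                fh.write(f"{rep}\t{s_r}\t{h_r}\n")
    path = out / "rarefaction_summary.json"
    written.append(path)
    with open(path, "w") as fh:
        json.dump({p: r.as_dict() for p, r in rarefactions.items()},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")

    # --- network -----------------------------------------------------------
    net = build_mjn(table, epsilon=cfg.epsilon)
    for fmt, name in (("graphml", "network.graphml"), ("dot", "network.dot"),
                      ("edge_tsv", "network_edges.tsv")):
        path = out / name
        written.append(path)
        export_network(net, path, fmt)
    path = out / "network_nodes.tsv"
    written.append(path)
    write_node_table(net, path)

    # --- manifest ----------------------------------------------------------
    path = out / "manifest.json"
    written.append(path)
    config_echo = {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in asdict(cfg).items()}
    with open(path, "w") as fh:
        json.dump(
            {
                "haplokit_version": __version__,
                "config": config_echo,
                "n_records": len(aln),
                "alignment_length": aln.length,
                "population_sizes": sizes,
                "n_variable_sites": len(sites),
                "n_haplotypes": len(table.labels),
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")

    return {
        "alignment": aln,
        "sites": sites,
        "haplotypes": table,
        "diversity": summaries,
        "fst": fst_results,
        "neutrality": neutrality,
        "rarefaction": rarefactions,
        "network": net,
    }
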