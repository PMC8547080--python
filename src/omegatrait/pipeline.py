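"""End-to-end orchestration: configuration, per-gene screening, reports.

``run_pipeline`` drives the full screen on a directory of per-gene codon
alignments: branch (two-ratio) tests with BH correction and REG calls,
branch-site tests with site posteriors and PSG calls, free-ratio fits
feeding root-to-tip omega tables, calibrated PGLS association for the two-
and three-class phenotype encodings, group-specific substitution scanning,
and — when family-count and gene-list inputs are provided — phylogenetic
ANOVA and overlap statistics.  Per-gene failures are isolated and logged,
never fatal; every run writes its resolved configuration and seed next to
the result tables, and reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import codon_model as cm
from .association import association_screen, phyl_anova, root_to_tip_omega
from .gene_sets import ExpansionSets, overlap_test, read_gene_list, shared_expanded_families
from .substitutions import records_to_frame, scan_specific_substitutions, translate_alignment
from .trees_io import (
    CodonAlignment,
    PhenotypeMap,
    PhyloTree,
    brownian_covariance,
    label_branches,
    restrict_to_taxa,
)


@dataclass
class PipelineConfig:
    """Resolved configuration for a pipeline run (YAML round-trippable)."""

    # inputs
    tree: str = ""
    alignments_dir: str = ""
    phenotypes: str = ""
    expansion_sets: str = ""          # optional TSV species/family_id/direction
    gene_lists: dict[str, str] = field(default_factory=dict)  # name -> path
    reference_species: str = ""       # for substitution coordinates
    # thresholds (the screen's fixed cutoffs)
    alpha: float = 0.05               # PGLS / LRT significance level
    fdr_q: float = 0.05               # BH-adjusted cutoff for REG/PSG
    min_rate: float = 2e-4            # dN/dS floor for root-to-tip averaging
    reg_ratio: float = 5.0            # omega_fg/omega_bg cutoff (strict >)
    reg_omega_floor: float = 0.5      # omega_fg cutoff (strict >)
    posterior_threshold: float = 0.8  # branch-site selected-codon posterior
    min_fg_fraction: float = 0.75     # substitution-scan foreground carriage
    min_bg_coverage: float = 0.8
    shared_expansion_k: int = 6       # families expanded in >= k group members
    # modelling options
    foreground_group: str = "ascrotal"
    foreground_mode: str = "tips_and_pure_clades"
    pi_mode: str = "f3x4"
    reestimate_lengths: bool = False
    require_robust: bool = False
    swap_response: bool = False       # regress omega on phenotype instead
    # execution
    nsim: int = 1000
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha", "fdr_q", "posterior_threshold",
                     "min_fg_fraction", "min_bg_coverage"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.min_rate < 0 or self.reg_ratio <= 0 or self.reg_omega_floor < 0:
            raise ValueError("invalid threshold configuration")
        if self.shared_expansion_k < 1 or self.nsim < 1:
            raise ValueError("shared_expansion_k and nsim must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


@dataclass
class RunLog:
    records: list[dict] = field(default_factory=list)

    def add(self, gene: str, stage: str, status: str, detail: str = "") -> None:
        self.records.append(
            {"gene": gene, "stage": stage, "status": status, "detail": detail}
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.records, columns=["gene", "stage", "status", "detail"]).to_csv(
            path, sep="\t", index=False
        )


def fit_gene_branch_models(
    aln: CodonAlignment,
    labeled_tree: PhyloTree,
    cfg: PipelineConfig,
    want_branch_site: bool = True,
    want_free_ratio: bool = True,
) -> dict:
    """All codon-model fits for one gene; shared one-ratio fit seeds the rest."""
    one = cm.fit_one_ratio(aln, labeled_tree, pi_mode=cfg.pi_mode)
    two = cm.fit_two_ratio(
        aln, labeled_tree, one_ratio=one, pi_mode=cfg.pi_mode,
        reestimate_lengths=cfg.reestimate_lengths,
    )
    out = {
        "one": one,
        "two": two,
        "branch_lrt": cm.lrt(one.lnL, two.lnL, df=1),
    }
    if want_branch_site:
        bs_null = cm.fit_branch_site(aln, labeled_tree, "null", one_ratio=one, pi_mode=cfg.pi_mode)
        bs_alt = cm.fit_branch_site(aln, labeled_tree, "alternative", one_ratio=one, pi_mode=cfg.pi_mode)
        out["bs_null"], out["bs_alt"] = bs_null, bs_alt
        out["bs_lrt"] = cm.lrt(bs_null.lnL, bs_alt.lnL, df=1)
        out["bs_posterior"] = cm.site_posteriors(bs_alt)
    if want_free_ratio:
        out["free"] = cm.fit_free_ratio(aln, labeled_tree, one_ratio=one, pi_mode=cfg.pi_mode)
    return out


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute the configured screen; returns the result tables in memory.

    Writes, under ``outdir``: branch_tests.tsv, branch_site_tests.tsv,
    omega_table.tsv, association_two_class.tsv / _three_class.tsv,
    substitutions.tsv, overlap_tests.tsv, phyl_anova.tsv,
    shared_expansions.tsv, summary.txt, resolved_config.yaml, run_log.tsv.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    tree = PhyloTree.from_newick(Path(cfg.tree).read_text())
    phenotypes = PhenotypeMap.from_tsv(cfg.phenotypes)
    missing_pheno = set(tree.tip_labels) - set(phenotypes.species)
    if missing_pheno:
        raise ValueError(f"tree tips without phenotype: {sorted(missing_pheno)}")
    fg_species = phenotypes.foreground_species(cfg.foreground_group)

    aln_paths = sorted(Path(cfg.alignments_dir).glob("*.fasta")) + sorted(
        Path(cfg.alignments_dir).glob("*.fa")
    )
    if not aln_paths:
        raise ValueError(f"no alignments found in {cfg.alignments_dir}")

    branch_rows, bs_rows, omega_rows, sub_frames = [], [], {}, []
    for path in aln_paths:
        gene = path.stem
        try:
            aln = CodonAlignment.from_fasta(path)
            gene_tree = (
                tree if set(aln.taxa) == set(tree.tip_labels)
                else restrict_to_taxa(tree, aln.taxa)
            )
            labeled = label_branches(
                gene_tree, fg_species & set(aln.taxa), cfg.foreground_mode
            )
            fits = fit_gene_branch_models(aln, labeled, cfg)
        except Exception as exc:
            log.add(gene, "codon_fits", "failed", f"{type(exc).__name__}: {exc}")
            continue
        one, two, blrt = fits["one"], fits["two"], fits["branch_lrt"]
        branch_rows.append(
            {
                "gene": gene,
                "lnL0": one.lnL,
                "lnL1": two.lnL,
                "kappa": two.params.kappa,
                "omega": one.omega,
                "omega_fg": two.extras["omega_fg"],
                "omega_bg": two.extras["omega_bg"],
                "stat": blrt.stat,
                "p": blrt.p,
            }
        )
        bs_rows.append(
            {
                "gene": gene,
                "lnL0": fits["bs_null"].lnL,
                "lnL1": fits["bs_alt"].lnL,
                "omega2": fits["bs_alt"].extras["omega2"],
                "stat": fits["bs_lrt"].stat,
                "p": fits["bs_lrt"].p,
                "_posterior": fits["bs_posterior"],
            }
        )
        rtt = root_to_tip_omega(fits["free"], labeled, min_rate=cfg.min_rate)
        omega_rows[gene] = rtt["omega"]
        try:
            aa = translate_alignment(aln)
            ref = cfg.reference_species or aln.taxa[0]
            recs = scan_specific_substitutions(
                aa, fg_species & set(aln.taxa), ref, gene=gene,
                min_fg_fraction=cfg.min_fg_fraction,
                min_bg_coverage=cfg.min_bg_coverage,
            )
            if recs:
                sub_frames.append(records_to_frame(recs))
        except Exception as exc:
            log.add(gene, "substitution_scan", "failed", f"{type(exc).__name__}: {exc}")
        log.add(gene, "codon_fits", "ok")

    results: dict = {}
    # ---- branch tests: BH across genes, REG rule
    branch_df = pd.DataFrame(branch_rows)
    if not branch_df.empty:
        branch_df["p_adj"] = cm.bh_adjust(branch_df["p"].to_numpy())
        reg = branch_df.apply(
            lambda r: cm.classify_reg(
                r["omega_fg"], r["omega_bg"], r["p_adj"],
                alpha=cfg.fdr_q, ratio_cutoff=cfg.reg_ratio,
                omega_floor=cfg.reg_omega_floor,
            ),
            axis=1,
        )
        branch_df["reg"] = [r[0] for r in reg]
        branch_df["reg_clause"] = [r[1] or "" for r in reg]
    branch_df.to_csv(outdir / "branch_tests.tsv", sep="\t", index=False)
    results["branch_tests"] = branch_df

    # ---- branch-site tests: BH, PSG rule, selected sites
    bs_df = pd.DataFrame([{k: v for k, v in row.items() if k != "_posterior"} for row in bs_rows])
    if not bs_df.empty:
        bs_df["p_adj"] = cm.bh_adjust(bs_df["p"].to_numpy())
        psg_flags, sites_col = [], []
        for row, padj in zip(bs_rows, bs_df["p_adj"]):
            is_psg, sites = cm.classify_psg(
                padj, row["_posterior"], alpha=cfg.fdr_q,
                posterior_threshold=cfg.posterior_threshold,
            )
            psg_flags.append(is_psg)
            sites_col.append(",".join(map(str, sites)))
        bs_df["psg"] = psg_flags
        bs_df["selected_sites"] = sites_col
    bs_df.to_csv(outdir / "branch_site_tests.tsv", sep="\t", index=False)
    results["branch_site_tests"] = bs_df

    # ---- association screens
    omega_table = pd.DataFrame(omega_rows).T
    omega_table.index.name = "gene"
    omega_table.to_csv(outdir / "omega_table.tsv", sep="\t")
    results["omega_table"] = omega_table
    C = brownian_covariance(tree)
    assoc = {}
    for scheme in ("two_class", "three_class"):
        y = phenotypes.encode(scheme)
        df = (
            association_screen(
                omega_table, y, C, alpha=cfg.alpha, require_robust=cfg.require_robust
            )
            if not omega_table.empty
            else pd.DataFrame()
        )
        df.to_csv(outdir / f"association_{scheme}.tsv", sep="\t", index=False)
        assoc[scheme] = df
    results["association"] = assoc

    # ---- substitutions
    subs_df = (
        pd.concat(sub_frames, ignore_index=True) if sub_frames else records_to_frame([])
    )
    subs_df.to_csv(outdir / "substitutions.tsv", sep="\t", index=False)
    results["substitutions"] = subs_df

    # ---- overlap tests of significant association genes vs provided lists
    overlap_rows = []
    sig_genes = {
        scheme: set(df.loc[df["significant"].astype(bool), "gene"])
        for scheme, df in assoc.items()
        if not df.empty
    }
    universe = list(omega_table.index)
    for list_name, list_path in cfg.gene_lists.items():
        genes = [g for g in read_gene_list(list_path) if g in set(universe)]
        for scheme, sig in sig_genes.items():
            if not sig:
                continue
            res = overlap_test(sorted(sig), genes, universe)
            overlap_rows.append(
                {
                    "list": list_name, "scheme": scheme,
                    "n_sig": res.n_a, "n_list": res.n_b,
                    "overlap": res.n_overlap, "universe": res.universe_size,
                    "odds_ratio": res.odds_ratio, "p": res.p,
                    "table": json.dumps(res.table),
                }
            )
    overlap_df = pd.DataFrame(overlap_rows)
    overlap_df.to_csv(outdir / "overlap_tests.tsv", sep="\t", index=False)
    results["overlap_tests"] = overlap_df

    # ---- gene-family counts: phylANOVA + shared expansions
    anova_rows, shared_rows = [], []
    if cfg.expansion_sets:
        expansion = ExpansionSets.from_tsv(cfg.expansion_sets)
        counts = expansion.counts()
        for scheme in ("two_class", "three_class"):
            grp_map = phenotypes.class2 if scheme == "two_class" else phenotypes.class3
            groups = pd.Series({sp: grp_map[sp] for sp in counts.index if sp in grp_map})
            for direction in ("expanded", "contracted"):
                vals = counts.loc[groups.index, direction].astype(float)
                try:
                    F, p = phyl_anova(
                        tree, vals, groups, nsim=cfg.nsim, seed=cfg.seed, C=C
                    )
                    anova_rows.append(
                        {"grouping": scheme, "direction": direction,
                         "F": F, "p": p, "nsim": cfg.nsim, "seed": cfg.seed}
                    )
                except ValueError as exc:
                    log.add("-", f"phyl_anova_{scheme}_{direction}", "failed", str(exc))
        group = phenotypes.foreground_species(cfg.foreground_group) & set(expansion.species)
        for fam in sorted(
            shared_expanded_families(expansion, group, cfg.shared_expansion_k)
        ):
            n = sum(fam in expansion.expanded.get(sp, set()) for sp in group)
            shared_rows.append(
                {"family_id": fam, "group": cfg.foreground_group,
                 "n_expanded": n, "group_size": len(group), "k": cfg.shared_expansion_k}
            )
    anova_df = pd.DataFrame(anova_rows)
    anova_df.to_csv(outdir / "phyl_anova.tsv", sep="\t", index=False)
    shared_df = pd.DataFrame(shared_rows)
    shared_df.to_csv(outdir / "shared_expansions.tsv", sep="\t", index=False)
    results["phyl_anova"] = anova_df
    results["shared_expansions"] = shared_df

    # ---- summary + provenance
    summary = render_summary(results, cfg)
    (outdir / "summary.txt").write_text(summary)
    results["summary"] = summary
    cfg.to_yaml(outdir / "resolved_config.yaml")
    log.to_tsv(outdir / "run_log.tsv")
    results["log"] = log
    return results


def render_summary(results: dict, cfg: PipelineConfig) -> str:
    """Plain-text counts of significant genes per analysis."""
    lines = ["# Screen summary", ""]
    bdf = results.get("branch_tests")
    if bdf is not None and not bdf.empty:
        n_reg = int(bdf["reg"].sum())
        by_clause = bdf.loc[bdf["reg"], "reg_clause"].value_counts().to_dict()
        lines.append(
            f"branch model: {len(bdf)} genes tested, {n_reg} REGs "
            f"(adjusted p < {cfg.fdr_q}); clauses: {by_clause}"
        )
    sdf = results.get("branch_site_tests")
    if sdf is not None and not sdf.empty:
        lines.append(
            f"branch-site model: {len(sdf)} genes tested, {int(sdf['psg'].sum())} PSGs "
            f"(adjusted p < {cfg.fdr_q}, site posterior > {cfg.posterior_threshold})"
        )
    assoc = results.get("association", {})
    sig_sets = {}
    for scheme, df in assoc.items():
        if df is None or df.empty:
            continue
        n_all = int((df["p_all"] < cfg.alpha).sum())
        n_max = int(df["significant"].astype(bool).sum())
        sig_sets[scheme] = set(df.loc[df["significant"].astype(bool), "gene"])
        lines.append(
            f"association ({scheme}): {len(df)} genes, {n_all} with p_all < {cfg.alpha}, "
            f"{n_max} significant after calibration (p_max < {cfg.alpha})"
        )
    if len(sig_sets) == 2:
        both = set.intersection(*sig_sets.values())
        union = set.union(*sig_sets.values())
        lines.append(
            f"association: {len(union)} genes significant in either encoding, "
            f"{len(both)} in both"
        )
    subs = results.get("substitutions")
    if subs is not None:
        lines.append(
            f"substitution scan: {len(subs)} group-specific records in "
            f"{subs['gene'].nunique() if not subs.empty else 0} genes"
        )
    odf = results.get("overlap_tests")
    if odf is not None and not odf.empty:
        for _, r in odf.iterrows():
            lines.append(
                f"overlap {r['list']} x {r['scheme']}: overlap {r['overlap']}, "
                f"OR {r['odds_ratio']:.3g}, p {r['p']:.3g}"
            )
    adf = results.get("phyl_anova")
    if adf is not None and not adf.empty:
        for _, r in adf.iterrows():
            lines.append(
                f"phylANOVA {r['grouping']}/{r['direction']}: F {r['F']:.3g}, p {r['p']:.4g}"
            )
    shared = results.get("shared_expansions")
    if shared is not None and not shared.empty:
        lines.append(
            f"shared expansions: {len(shared)} families expanded in >= "
            f"{cfg.shared_expansion_k} {cfg.foreground_group} species"
        )
    return "\n".join(lines) + "\n"
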