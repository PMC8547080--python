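"""Seeded generators for every input the pipeline consumes.

All stages of the screen can be exercised without any external download:
codon alignments evolved along a labeled tree under chosen per-branch
omega/kappa/pi, clade-structured phenotypes on a bundled 30-tip tree,
per-gene root-to-tip omega tables with a planted phenotype association in a
controlled fraction of genes, overdispersed gene-family count matrices, and
gene lists with exact requested intersections.  Every generator takes a seed
(or numpy Generator) and records its ground truth, so recovery tests know
the answer.

Branch evolution samples child codons directly from the exponentiated
generator matrix (exact for a site-independent model); stop codons cannot
arise because the chain lives on the 61 sense codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_model import CodonRateModel
from .trees_io import (
    CodonAlignment,
    PhenotypeMap,
    PhyloTree,
    brownian_covariance,
    FOREGROUND,
)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class SimTruth:
    """Ground truth recorded by a generator, reproducible from (seed, params)."""

    seed: int | None
    params: dict = field(default_factory=dict)
    branch_omega: dict[int, float] | None = None
    signal_genes: list[str] | None = None
    planted_columns: list[int] | None = None
    extra: dict = field(default_factory=dict)


# ------------------------------------------------------------------- trees


def simulate_tree(n_tips: int, seed=0, depth: float = 1.0) -> PhyloTree:
    """Pure-birth (Yule) ultrametric tree scaled to the given root-to-tip depth."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = _rng(seed)
    parent = [-1, 0, 0]
    birth = [0.0, 0.0, 0.0]
    active = [1, 2]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        v = active.pop(k)
        for _ in range(2):
            parent.append(v)
            birth.append(t)
            active.append(len(parent) - 1)
    t += rng.exponential(1.0 / len(active))
    if t <= 0:
        t = 1e-9
    length = np.zeros(len(parent))
    names: list[str | None] = [None] * len(parent)
    end = {v: t for v in active}
    tip_no = 0
    for v in range(len(parent)):
        if v in end:
            tip_no += 1
            names[v] = f"sp{tip_no:02d}"
    for v, p in enumerate(parent):
        if p < 0:
            continue
        top = birth[v]
        bottom = end.get(v)
        if bottom is None:  # internal: ends when it splits, i.e. its children's birth
            kids = [u for u, q in enumerate(parent) if q == v]
            bottom = birth[kids[0]]
        length[v] = bottom - top
    scale = depth / t
    length *= scale
    return PhyloTree(np.array(parent), length, names)


# 30-tip working phylogeny with clade-structured testicular-position labels:
# a wholly-ascrotal aquatic-style clade mixing IDT and UDT (sp06-sp10),
# pure IDT pairs (sp04/sp05, sp14/sp15), a UDT pair (sp20/sp21) and
# scattered IDT singletons (sp17, sp26) inside otherwise scrotal clades, so
# both foreground-labeling modes are exercised.  Depth 100 time units.
_FIXTURE_NEWICK = (
    "((((sp01:12,sp02:12):20,(sp03:18,(sp04:10,sp05:10):8):14):28,"
    "((sp06:9,sp07:9):16,(sp08:14,(sp09:7,sp10:7):7):11):35):40,"
    "(((sp11:22,(sp12:13,sp13:13):9):24,((sp14:16,sp15:16):17,"
    "(sp16:20,(sp17:11,sp18:11):9):13):13):32,((sp19:26,((sp20:8,sp21:8):10,"
    "sp22:18):8):28,((sp23:17,(sp24:9,sp25:9):8):21,((sp26:12,sp27:12):15,"
    "(sp28:16,(sp29:10,sp30:10):6):11):11):16):24):22):0;"
)

# 17 scrotal (CDT), 9 IDT, 4 UDT — the study-like phenotype layout
_FIXTURE_CLASS3 = {
    "sp04": "IDT", "sp05": "IDT",                 # IDT pair inside a scrotal clade
    "sp06": "IDT", "sp07": "IDT", "sp08": "IDT",  # wholly-ascrotal clade ...
    "sp09": "UDT", "sp10": "UDT",                 # ... mixing IDT and UDT
    "sp14": "IDT", "sp15": "IDT",                 # second pure IDT pair
    "sp17": "IDT",                                # scattered IDT singleton
    "sp20": "UDT", "sp21": "UDT",                 # UDT pair
    "sp26": "IDT",                                # scattered IDT singleton
}


def fixture_tree() -> PhyloTree:
    """The bundled 30-tip ultrametric tree (depth 100 time units)."""
    return PhyloTree.from_newick(_FIXTURE_NEWICK)


def fixture_phenotypes() -> PhenotypeMap:
    """Clade-structured phenotypes for the fixture tree (17 CDT, 9 IDT, 4 UDT)."""
    tree = fixture_tree()
    class3 = {sp: _FIXTURE_CLASS3.get(sp, "CDT") for sp in tree.tip_labels}
    class2 = {sp: ("scrotal" if c == "CDT" else "ascrotal") for sp, c in class3.items()}
    return PhenotypeMap(class2=class2, class3=class3)


# -------------------------------------------------------- codon alignments


def class_omega(tree: PhyloTree, omega_bg: float, omega_fg: float) -> dict[int, float]:
    """Per-branch omega map from the tree's foreground/background labels."""
    return {
        v: (omega_fg if tree.branch_class[v] == FOREGROUND else omega_bg)
        for v in tree.branch_indices()
    }


def _resolve_branch_omega(tree: PhyloTree, omega) -> dict[int, float]:
    if isinstance(omega, dict):
        missing = set(tree.branch_indices()) - set(omega)
        if missing:
            raise ValueError(f"omega map missing branches: {sorted(missing)}")
        return {v: float(omega[v]) for v in tree.branch_indices()}
    return {v: float(omega) for v in tree.branch_indices()}


def simulate_codon_alignment(
    tree: PhyloTree,
    omega,
    kappa: float = 2.0,
    pi: np.ndarray | None = None,
    n_codons: int = 300,
    seed=0,
) -> tuple[CodonAlignment, SimTruth]:
    """Evolve a codon alignment along the tree under GY94 dynamics.

    ``omega`` is a scalar or a per-branch map (node index -> omega, e.g.
    from :func:`class_omega`).  Root codons are drawn from pi; each branch
    multiplies by the transition matrix of the scaled generator at its
    (t, omega).  Site-independent and fully seeded.
    """
    rng = _rng(seed)
    pi = np.full(61, 1 / 61) if pi is None else np.asarray(pi, dtype=float)
    branch_omega = _resolve_branch_omega(tree, omega)
    models = {w: CodonRateModel(kappa, w, pi) for w in set(branch_omega.values())}
    states = {tree.root: rng.choice(61, size=n_codons, p=pi / pi.sum())}
    for v in tree.preorder:
        if v == tree.root:
            continue
        P = models[branch_omega[v]].transition_matrix(float(tree.length[v]))
        cum = np.cumsum(P, axis=1)
        cum[:, -1] = 1.0
        u = rng.random(n_codons)
        rows = cum[states[tree.parent[v]]]
        states[v] = (rows < u[:, None]).sum(axis=1).astype(np.int16)
    taxa = list(tree.tip_labels)
    mat = np.vstack([states[tree.tip_index(t)] for t in taxa])
    truth = SimTruth(
        seed=None,
        params={"kappa": kappa, "n_codons": n_codons},
        branch_omega=branch_omega,
    )
    return CodonAlignment(taxa, mat), truth


def simulate_branch_site_alignment(
    tree: PhyloTree,
    prop_selected: float,
    omega0: float,
    omega2: float,
    kappa: float = 2.0,
    pi: np.ndarray | None = None,
    n_codons: int = 300,
    seed=0,
) -> tuple[CodonAlignment, SimTruth]:
    """Alignment with a planted fraction of foreground-positively-selected sites.

    The last ``round(prop_selected * n_codons)`` codon columns evolve with
    omega2 on foreground branches (omega0 on the background); all other
    columns evolve with omega0 everywhere.  Planted 1-based columns are
    recorded in the truth.
    """
    rng = _rng(seed)
    n_sel = int(round(prop_selected * n_codons))
    aln_bg, _ = simulate_codon_alignment(
        tree, omega0, kappa=kappa, pi=pi, n_codons=n_codons - n_sel, seed=rng
    )
    omega_map = class_omega(tree, omega0, omega2)
    aln_sel, _ = simulate_codon_alignment(
        tree, omega_map, kappa=kappa, pi=pi, n_codons=n_sel, seed=rng
    )
    mat = np.hstack([aln_bg.codons, aln_sel.codons])
    planted = list(range(n_codons - n_sel + 1, n_codons + 1))
    truth = SimTruth(
        seed=None,
        params={
            "kappa": kappa, "omega0": omega0, "omega2": omega2,
            "prop_selected": prop_selected, "n_codons": n_codons,
        },
        planted_columns=planted,
    )
    return CodonAlignment(aln_bg.taxa, mat), truth


# --------------------------------------------- trait-rate association data


def simulate_trait_rate_dataset(
    tree: PhyloTree,
    phenotype: pd.Series,
    n_genes: int,
    signal_fraction: float = 0.1,
    effect_size: float = 0.1,
    noise_sd: float = 0.05,
    seed=0,
    base_omega: float = 0.2,
    outlier_species: str | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Per-gene x species root-to-tip omega table with planted associations.

    Null genes are Brownian-correlated noise around ``base_omega`` (tip
    variance ``noise_sd**2``); signal genes add ``effect_size`` times the
    numeric phenotype encoding — or, when ``outlier_species`` is given, the
    full effect to that single species only (the pathological construction
    the leave-one-out calibration is built to reject).  Values are floored
    at a small positive omega.
    """
    rng = _rng(seed)
    species = list(phenotype.index)
    C = brownian_covariance(tree, labels=species).to_numpy()
    depth = float(np.max(np.diag(C)))
    L = np.linalg.cholesky(C / depth + 1e-12 * np.eye(len(species)))
    n_signal = int(round(signal_fraction * n_genes))
    genes = [f"gene{i + 1:04d}" for i in range(n_genes)]
    signal = set(genes[:n_signal])
    y = phenotype.to_numpy(dtype=float)
    rows = []
    for g in genes:
        x = base_omega + noise_sd * (L @ rng.standard_normal(len(species)))
        if g in signal:
            if outlier_species is None:
                x = x + effect_size * y
            else:
                x[species.index(outlier_species)] += effect_size
        rows.append(np.clip(x, 1e-3, None))
    table = pd.DataFrame(rows, index=genes, columns=species)
    truth = SimTruth(
        seed=None,
        params={
            "n_genes": n_genes, "signal_fraction": signal_fraction,
            "effect_size": effect_size, "noise_sd": noise_sd,
            "base_omega": base_omega, "outlier_species": outlier_species,
        },
        signal_genes=sorted(signal),
    )
    return table, truth


# ------------------------------------------------------ gene-family counts


def simulate_family_counts(
    tree: PhyloTree,
    groups: pd.Series,
    shift: dict[str, float] | None = None,
    dispersion: float = 8.0,
    seed=0,
    base_mean: float = 120.0,
    n_families: int = 4000,
    force_expanded: dict[str, set[str]] | None = None,
):
    """Overdispersed per-species expansion/contraction counts + family sets.

    Counts are gamma-Poisson (negative-binomial-like) with mean
    ``base_mean + shift[group]`` for expansions and ``base_mean`` for
    contractions.  Family IDs realizing the counts are drawn from a shared
    universe, never overlapping within a species; ``force_expanded`` plants
    specific families as expanded in specific species (for shared-expansion
    detection tests).  Returns (counts DataFrame, ExpansionSets, SimTruth).
    """
    from .gene_sets import ExpansionSets

    rng = _rng(seed)
    shift = shift or {}
    families = [f"FAM{i + 1:05d}" for i in range(n_families)]
    expanded: dict[str, set[str]] = {}
    contracted: dict[str, set[str]] = {}
    force_expanded = force_expanded or {}
    for sp in groups.index:
        mu_e = max(base_mean + float(shift.get(str(groups[sp]), 0.0)), 1.0)
        lam_e = rng.gamma(dispersion, mu_e / dispersion)
        lam_c = rng.gamma(dispersion, base_mean / dispersion)
        n_e = int(rng.poisson(lam_e))
        n_c = int(rng.poisson(lam_c))
        forced = {f for f, spp in force_expanded.items() if sp in spp}
        pool = [f for f in families if f not in forced]
        pick = rng.choice(len(pool), size=min(n_e + n_c, len(pool)), replace=False)
        exp_extra = {pool[i] for i in pick[: max(n_e - len(forced), 0)]}
        con = {pool[i] for i in pick[max(n_e - len(forced), 0) : n_e + n_c - len(forced)]}
        expanded[sp] = forced | exp_extra
        contracted[sp] = con - expanded[sp]
    sets = ExpansionSets(expanded=expanded, contracted=contracted)
    truth = SimTruth(
        seed=None,
        params={
            "shift": shift, "dispersion": dispersion, "base_mean": base_mean,
            "n_families": n_families,
        },
        extra={"force_expanded": {f: sorted(s) for f, s in force_expanded.items()}},
    )
    return sets.counts(), sets, truth


# ------------------------------------------------------------ input bundles


def assign_clade_phenotypes(
    tree: PhyloTree, n_idt: int = 2, n_udt: int = 2
) -> PhenotypeMap:
    """Clade-structured phenotype assignment for a simulated tree.

    Greedily assigns cherries (two-tip clades) to IDT, then UDT, topping up
    with scattered singleton tips; all remaining species are scrotal CDT.
    """
    if n_idt + n_udt >= tree.n_tips:
        raise ValueError("ascrotal groups must leave at least one scrotal tip")
    cherries = [
        v
        for v in range(tree.n_nodes)
        if tree.children[v]
        and len(tree.children[v]) == 2
        and all(not tree.children[c] for c in tree.children[v])
    ]
    class3 = {sp: "CDT" for sp in tree.tip_labels}

    def take(label: str, want: int) -> None:
        left = want
        while left >= 2 and cherries:
            v = cherries.pop(0)
            for c in tree.children[v]:
                class3[tree.names[c]] = label
            left -= 2
        if left > 0:
            for sp in tree.tip_labels:
                if left and class3[sp] == "CDT":
                    class3[sp] = label
                    left -= 1

    take("IDT", n_idt)
    take("UDT", n_udt)
    class2 = {sp: ("scrotal" if c == "CDT" else "ascrotal") for sp, c in class3.items()}
    return PhenotypeMap(class2=class2, class3=class3)


def write_bundle(
    outdir,
    n_genes: int = 10,
    n_codons: int = 300,
    reg_fraction: float = 0.2,
    omega_bg: float = 0.2,
    omega_fg: float = 0.8,
    kappa: float = 2.0,
    codon_tree_scale: float = 0.004,
    seed: int = 0,
    foreground_mode: str = "tips_and_pure_clades",
    n_tips: int | None = None,
) -> dict:
    """Write a complete synthetic input set for the pipeline.

    Under ``outdir``: tree.nwk (the 30-tip fixture by default, or a
    simulated ``n_tips`` tree with clade-structured phenotypes; time units),
    phenotypes.tsv, alignments/<gene>.fasta evolved on the time tree
    rescaled by ``codon_tree_scale`` substitutions per codon per time unit
    (a fraction ``reg_fraction`` of genes gets ``omega_fg`` on ascrotal
    branches), expansion.tsv family sets, two gene lists, and a
    truth.tsv sidecar naming the planted rapid-evolution genes.
    """
    from pathlib import Path

    from .trees_io import label_branches

    rng = _rng(seed)
    outdir = Path(outdir)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    if n_tips is None:
        tree = fixture_tree()
        pheno = fixture_phenotypes()
    else:
        tree = simulate_tree(n_tips, seed=rng, depth=100.0)
        pheno = assign_clade_phenotypes(
            tree, n_idt=max(2, n_tips // 4), n_udt=max(2, n_tips // 4)
        )
    (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
    pheno.to_tsv(outdir / "phenotypes.tsv")
    codon_tree = tree.copy()
    codon_tree.length = codon_tree.length * codon_tree_scale
    labeled = label_branches(
        codon_tree, pheno.foreground_species("ascrotal"), foreground_mode
    )
    n_reg = int(round(reg_fraction * n_genes))
    truth_rows = []
    for i in range(n_genes):
        gene = f"gene{i + 1:04d}"
        planted = i < n_reg
        omega = (
            class_omega(labeled, omega_bg, omega_fg) if planted else omega_bg
        )
        aln, _ = simulate_codon_alignment(
            labeled, omega, kappa=kappa, n_codons=n_codons, seed=rng
        )
        aln.to_fasta(outdir / "alignments" / f"{gene}.fasta")
        truth_rows.append({"gene": gene, "planted_reg": planted,
                           "omega_fg": omega_fg if planted else omega_bg,
                           "omega_bg": omega_bg})
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    groups = pd.Series(pheno.class3)
    _, sets, _ = simulate_family_counts(tree, groups, seed=rng)
    sets.to_tsv(outdir / "expansion.tsv")
    list_a, list_b, universe, _ = simulate_gene_lists(
        max(n_genes, 20), max(n_genes // 2, 5), max(n_genes // 2, 5),
        max(n_genes // 5, 2), seed=rng,
    )
    genes = [f"gene{i + 1:04d}" for i in range(max(n_genes, 20))]
    remap = dict(zip([f"g{i + 1:05d}" for i in range(len(genes))], genes))
    from .gene_sets import write_gene_list

    write_gene_list([remap[g] for g in list_a], outdir / "list_a.txt")
    write_gene_list([remap[g] for g in list_b], outdir / "list_b.txt")
    return {
        "tree": str(outdir / "tree.nwk"),
        "phenotypes": str(outdir / "phenotypes.tsv"),
        "alignments_dir": str(outdir / "alignments"),
        "expansion_sets": str(outdir / "expansion.tsv"),
        "gene_lists": {"list_a": str(outdir / "list_a.txt"),
                       "list_b": str(outdir / "list_b.txt")},
        "truth": str(outdir / "truth.tsv"),
    }


# --------------------------------------------------------------- gene lists


def simulate_gene_lists(
    universe_size: int, size_a: int, size_b: int, overlap: int, seed=0
) -> tuple[list[str], list[str], list[str], SimTruth]:
    """Two gene lists from a universe with an exact requested intersection."""
    if overlap > min(size_a, size_b):
        raise ValueError("overlap exceeds the smaller list")
    if size_a + size_b - overlap > universe_size:
        raise ValueError("lists cannot fit in the universe with this overlap")
    rng = _rng(seed)
    universe = [f"g{i + 1:05d}" for i in range(universe_size)]
    perm = rng.permutation(universe_size)
    shared = [universe[i] for i in perm[:overlap]]
    a_only = [universe[i] for i in perm[overlap : size_a]]
    b_only = [universe[i] for i in perm[size_a : size_a + size_b - overlap]]
    list_a = sorted(shared + a_only)
    list_b = sorted(shared + b_only)
    truth = SimTruth(
        seed=None,
        params={
            "universe_size": universe_size, "size_a": size_a,
            "size_b": size_b, "overlap": overlap,
        },
    )
    return list_a, list_b, universe, truth
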