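"""Synthetic paired scTCR-seq data with recorded ground truth.

This module emulates the statistical structure of a multi-donor, matched
blood/liver MAIT-cell dataset: semi-invariant TRAV1-2 alpha chains joined to
TRAJ33/TRAJ12/TRAJ20 (default usage 0.87/0.06/0.06) with 12-amino-acid CDR3
regions carrying the canonical Tyr residue; diverse beta chains biased toward
TRBV6-1, TRBV6-4 and TRBV20-1, with extra TRBV6-4 pairing for TRAJ12/TRAJ20
alphas; skewed (log-series) clone sizes; matched-tissue clonal overlap;
multi-donor public alpha chains; per-chain dropout; TCR capture failures; and
chain-merging doublets. Companion generators emit cluster labels with planted
clonotype bias, pseudotime tables with planted clonotype/TRBV shifts, regulon
runs with stable cores and noisy peripheries, and expression matrices honoring
coreceptor-assignment thresholds and planted regulon-activity shifts.

Every generator is deterministic given its seed, and every planted quantity is
recorded in a ground-truth object so recovery can be tested without real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGT"

CONTIG_COLUMNS = [
    "barcode", "is_cell", "contig_id", "high_confidence", "length", "chain",
    "v_gene", "d_gene", "j_gene", "c_gene", "full_length", "productive",
    "cdr3", "cdr3_nt", "reads", "umis", "raw_clonotype_id", "raw_consensus_id",
]

DEFAULT_TRAJ_PROBS = {"TRAJ33": 0.87, "TRAJ12": 0.06, "TRAJ20": 0.06, "TRAJ27": 0.01}
DEFAULT_TRBV_PROBS = {
    "TRBV6-1": 0.18, "TRBV6-4": 0.16, "TRBV20-1": 0.14, "TRBV28": 0.08,
    "TRBV19": 0.08, "TRBV4-1": 0.07, "TRBV5-1": 0.07, "TRBV9": 0.06,
    "TRBV2": 0.06, "TRBV7-2": 0.05, "TRBV25-1": 0.05,
}
#: multiplicative boost of TRBV6-4 for TRAJ12/TRAJ20 alpha chains
DEFAULT_PAIRING_BOOST = {"TRAJ12": {"TRBV6-4": 3.0}, "TRAJ20": {"TRBV6-4": 3.0}}
TRBJ_GENES = ["TRBJ1-1", "TRBJ1-2", "TRBJ2-1", "TRBJ2-3", "TRBJ2-7"]


@dataclass
class RepertoireConfig:
    """Study-condition parameters of the synthetic repertoire."""

    donors: int = 6
    clones_per_donor: int = 150
    cells_per_sample: int = 2000
    tissues: tuple[str, ...] = ("blood", "liver")
    traj_probs: dict = field(default_factory=lambda: dict(DEFAULT_TRAJ_PROBS))
    trbv_probs: dict = field(default_factory=lambda: dict(DEFAULT_TRBV_PROBS))
    pairing_boost: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PAIRING_BOOST.items()})
    public_alpha_count: int = 5
    tissue_overlap: float = 0.7
    shared_clone_fraction: float = 0.4
    dropout: float = 0.1
    doublet_rate: float = 0.01
    capture_rate: float = 0.9
    dual_alpha_rate: float = 0.3
    dual_beta_rate: float = 0.1
    logseries_p: float = 0.92
    condition: str = "unstimulated"
    timepoint: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for probs in (self.traj_probs, self.trbv_probs):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"probability vector sums to {total}, not 1")
        for rate in (self.tissue_overlap, self.dropout, self.doublet_rate, self.capture_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.public_alpha_count > self.clones_per_donor:
            raise ValueError("more public alpha chains than clones per donor")


@dataclass
class GroundTruth:
    """Planted structure of a generated repertoire."""

    partition: dict = field(default_factory=dict)  # barcode -> clone id
    clone_chains_nt: dict = field(default_factory=dict)  # clone id -> [[locus,v,j,cdr3nt], ...]
    clone_chains_aa: dict = field(default_factory=dict)
    donor_of: dict = field(default_factory=dict)
    tissue_of: dict = field(default_factory=dict)
    doublet_barcodes: list = field(default_factory=list)
    detectable_doublets: int = 0
    cells_total: dict = field(default_factory=dict)  # "donor|tissue" -> generated cells
    public_alpha_aa: list = field(default_factory=list)  # [locus, v, j, cdr3aa] keys
    shared_clones: dict = field(default_factory=dict)  # donor -> [clone ids]
    config: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)  # cluster/pseudotime/regulon truths

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "GroundTruth":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        return cls(**data)


def _random_seq(rng: np.random.Generator, alphabet: str, length: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def _unique_seq(rng, alphabet, length, used: set) -> str:
    while True:
        s = _random_seq(rng, alphabet, length)
        if s not in used:
            used.add(s)
            return s


def _mait_cdr3a(rng, used_aa: set) -> str:
    # 12-aa CDR3alpha: Cys start, canonical Tyr near the J junction, Phe end
    while True:
        middle = _random_seq(rng, AA_ALPHABET, 8)
        s = "CA" + middle[:7] + "Y" + middle[7] + "F"
        assert len(s) == 12
        if s not in used_aa:
            used_aa.add(s)
            return s


def _draw(rng, probs: dict) -> str:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _make_clone(rng, cfg: RepertoireConfig, used_nt: set, used_aa: set,
                public_alpha=None) -> dict:
    """One clone: chain descriptors [locus, v, j, cdr3_nt, cdr3_aa]."""
    chains = []
    if public_alpha is not None:
        # public clones stay single-alpha so dropout can never hide the
        # planted public chain from a captured cell
        chains.append(list(public_alpha))
        traj = public_alpha[2]
    else:
        traj = _draw(rng, cfg.traj_probs)
        chains.append(["TRA", "TRAV1-2", traj,
                       _unique_seq(rng, NT_ALPHABET, 36, used_nt),
                       _mait_cdr3a(rng, used_aa)])
    dual_alpha = public_alpha is None and rng.random() < cfg.dual_alpha_rate
    if dual_alpha:
        traj2 = _draw(rng, cfg.traj_probs)
        chains.append(["TRA", "TRAV1-2", traj2,
                       _unique_seq(rng, NT_ALPHABET, 36, used_nt),
                       _mait_cdr3a(rng, used_aa)])
    trbv_probs = dict(cfg.trbv_probs)
    for gene, factor in cfg.pairing_boost.get(traj, {}).items():
        trbv_probs[gene] = trbv_probs.get(gene, 0.0) * factor
    # a genuine cell never carries 2 alpha AND 2 beta chains (that chain
    # pattern defines a doublet), so dual-alpha clones stay single-beta
    n_beta = 2 if (not dual_alpha and rng.random() < cfg.dual_beta_rate) else 1
    for _ in range(n_beta):
        length = int(rng.integers(12, 17))
        aa = "CASS" + _unique_seq(rng, AA_ALPHABET, length - 5, used_aa) + "F"
        chains.append(["TRB", _draw(rng, trbv_probs), TRBJ_GENES[rng.integers(len(TRBJ_GENES))],
                       _unique_seq(rng, NT_ALPHABET, 3 * length, used_nt), aa])
    return {"chains": chains}


def generate_repertoire(cfg: RepertoireConfig):
    """Emit a 10x-style contig table, per-cell metadata and the ground truth.

    Returns ``(contigs, meta, truth)`` where ``contigs`` and ``meta`` are
    DataFrames in the formats read by :mod:`clonolink.contig_io`.
    """
    rng = np.random.default_rng(cfg.seed)
    used_nt: set = set()
    used_aa: set = set()
    truth = GroundTruth(config=asdict(cfg))

    # public alpha chains shared (aa and nt) by one clone in every donor
    public_alphas = []
    for _ in range(cfg.public_alpha_count):
        traj = _draw(rng, cfg.traj_probs)
        public_alphas.append(["TRA", "TRAV1-2", traj,
                              _unique_seq(rng, NT_ALPHABET, 36, used_nt),
                              _mait_cdr3a(rng, used_aa)])
    truth.public_alpha_aa = [[a[0], a[1], a[2], a[4]] for a in public_alphas]

    contig_rows: list[dict] = []
    meta_rows: list[dict] = []

    for d in range(cfg.donors):
        donor = f"d{d + 1}"
        clones = {}
        for c in range(cfg.clones_per_donor):
            clone_id = f"{donor}_c{c}"
            public = public_alphas[c] if c < cfg.public_alpha_count else None
            clones[clone_id] = _make_clone(rng, cfg, used_nt, used_aa, public)
            truth.clone_chains_nt[clone_id] = [
                [ch[0], ch[1], ch[2], ch[3]] for ch in clones[clone_id]["chains"]
            ]
            truth.clone_chains_aa[clone_id] = [
                [ch[0], ch[1], ch[2], ch[4]] for ch in clones[clone_id]["chains"]
            ]

        clone_ids = list(clones)
        weights = stats.logser.rvs(cfg.logseries_p, size=len(clone_ids), random_state=rng).astype(float)
        n_shared = max(cfg.public_alpha_count, int(round(cfg.shared_clone_fraction * len(clone_ids))))
        shared_ids = clone_ids[:n_shared]
        private = clone_ids[n_shared:]
        half = len(private) // 2
        private_pool = {"blood": private[:half] or shared_ids,
                        "liver": private[half:] or shared_ids}
        for t in cfg.tissues:
            if t not in private_pool:
                private_pool[t] = private or shared_ids
        truth.shared_clones[donor] = shared_ids
        w = dict(zip(clone_ids, weights))

        def pool_probs(ids):
            v = np.array([w[i] for i in ids], dtype=float)
            return v / v.sum()

        shared_p = pool_probs(shared_ids)
        sample_cells: dict[str, list[tuple[str, str]]] = {}
        for tissue in cfg.tissues:
            priv_ids = private_pool[tissue]
            priv_p = pool_probs(priv_ids)
            cells = []
            guaranteed = set()
            for i in range(cfg.cells_per_sample):
                barcode = f"{donor}-{tissue}-{i:05d}"
                if i < cfg.public_alpha_count and tissue == cfg.tissues[0]:
                    clone = shared_ids[i]  # guarantee every public clone appears
                    guaranteed.add(barcode)
                elif rng.random() < cfg.tissue_overlap:
                    clone = shared_ids[rng.choice(len(shared_ids), p=shared_p)]
                else:
                    clone = priv_ids[rng.choice(len(priv_ids), p=priv_p)]
                cells.append((barcode, clone))
            sample_cells[tissue] = (cells, guaranteed)
            truth.cells_total[f"{donor}|{tissue}"] = len(cells)

        for tissue, (cells, guaranteed) in sample_cells.items():
            captured = []
            for barcode, clone in cells:
                meta_rows.append(
                    {"barcode": barcode, "donor": donor, "tissue": tissue,
                     "condition": cfg.condition, "timepoint": cfg.timepoint}
                )
                if barcode not in guaranteed and rng.random() >= cfg.capture_rate:
                    continue  # no TCR recovered for this cell
                truth.partition[barcode] = clone
                truth.donor_of[barcode] = donor
                truth.tissue_of[barcode] = tissue
                chains = _apply_dropout(rng, clones[clone]["chains"], cfg.dropout)
                captured.append((barcode, chains))
                contig_rows.extend(_contig_rows(rng, barcode, chains))

            n_doublets = rng.binomial(len(captured), cfg.doublet_rate) if len(captured) >= 2 else 0
            for j in range(n_doublets):
                i1, i2 = rng.choice(len(captured), size=2, replace=False)
                merged = {tuple(ch[:4]): ch for ch in captured[i1][1] + captured[i2][1]}
                barcode = f"{donor}-{tissue}-dbl{j:04d}"
                meta_rows.append(
                    {"barcode": barcode, "donor": donor, "tissue": tissue,
                     "condition": cfg.condition, "timepoint": cfg.timepoint}
                )
                chains = list(merged.values())
                n_a = sum(1 for ch in chains if ch[0] == "TRA")
                n_b = sum(1 for ch in chains if ch[0] == "TRB")
                truth.doublet_barcodes.append(barcode)
                if (n_a == 2 and n_b == 2) or n_a > 2 or n_b > 2:
                    truth.detectable_doublets += 1
                contig_rows.extend(_contig_rows(rng, barcode, chains))

    contigs = pd.DataFrame(contig_rows, columns=CONTIG_COLUMNS)
    meta = pd.DataFrame(meta_rows)
    return contigs, meta, truth


def _apply_dropout(rng, chains, rate):
    """Drop chains at the per-chain rate but keep at least one per locus."""
    if rate <= 0:
        return [list(ch) for ch in chains]
    kept = [list(ch) for ch in chains if rng.random() >= rate]
    for locus in ("TRA", "TRB"):
        if not any(ch[0] == locus for ch in kept):
            first = next((ch for ch in chains if ch[0] == locus), None)
            if first is not None:
                kept.append(list(first))
    return kept


def _contig_rows(rng, barcode, chains):
    rows = []
    for j, (locus, v, jgene, nt, aa) in enumerate(chains):
        umis = int(rng.integers(1, 50))
        rows.append(
            {
                "barcode": barcode,
                "is_cell": "True",
                "contig_id": f"{barcode}_contig_{j + 1}",
                "high_confidence": "True",
                "length": len(nt) + 400,
                "chain": locus,
                "v_gene": v,
                "d_gene": "TRBD1" if locus == "TRB" else "None",
                "j_gene": jgene,
                "c_gene": "TRBC1" if locus == "TRB" else "TRAC",
                "full_length": "True",
                "productive": "True",
                "cdr3": aa,
                "cdr3_nt": nt,
                "reads": umis * 30,
                "umis": umis,
                "raw_clonotype_id": "None",
                "raw_consensus_id": "None",
            }
        )
    return rows


def write_contig_csv(contigs: pd.DataFrame, path) -> None:
    contigs.to_csv(path, index=False)


def write_meta_csv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)


DEFAULT_CLUSTER_PROPS = (0.25, 0.20, 0.15, 0.12, 0.10, 0.08, 0.06, 0.04)


def generate_cluster_labels(
    barcodes,
    clonotype_of: dict,
    n_clusters: int = 8,
    cluster_props=None,
    biased_clonotypes=(),
    bias_concentration: float = 0.1,
    forced_cluster: dict | None = None,
    exact_proportions: bool = False,
    seed: int = 0,
):
    """Assign per-cell cluster labels with optional planted clonotype bias.

    Unbiased cells draw clusters from the global proportions (or, with
    ``exact_proportions``, by permuting a fixed label vector so empirical
    proportions are exact). Each clonotype in ``biased_clonotypes`` draws its
    cells from a Dirichlet-perturbed proposal with concentration parameter
    ``bias_concentration * proportions`` (small values concentrate the
    clonotype in few clusters). ``forced_cluster`` maps clonotype id ->
    cluster index for fully concentrated planting. Returns ``(labels, truth)``
    where ``labels`` maps barcode -> cluster index.
    """
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    rng = np.random.default_rng(seed)
    if cluster_props is None:
        cluster_props = DEFAULT_CLUSTER_PROPS[:n_clusters]
    props = np.asarray(cluster_props, dtype=float)
    props = props / props.sum()
    if props.size != n_clusters:
        raise ValueError("cluster_props length must equal n_clusters")
    barcodes = list(barcodes)
    forced_cluster = forced_cluster or {}
    biased = set(biased_clonotypes) | set(forced_cluster)

    labels: dict = {}
    unbiased = [bc for bc in barcodes if clonotype_of.get(bc) not in biased]
    if exact_proportions:
        counts = np.floor(props * len(unbiased)).astype(int)
        while counts.sum() < len(unbiased):
            counts[int(np.argmax(props * len(unbiased) - counts))] += 1
        pool = np.repeat(np.arange(n_clusters), counts)
        rng.shuffle(pool)
        for bc, cl in zip(unbiased, pool):
            labels[bc] = int(cl)
    else:
        draws = rng.choice(n_clusters, size=len(unbiased), p=props)
        for bc, cl in zip(unbiased, draws):
            labels[bc] = int(cl)

    proposals: dict = {}
    for bc in barcodes:
        cid = clonotype_of.get(bc)
        if cid not in biased:
            continue
        if cid in forced_cluster:
            labels[bc] = int(forced_cluster[cid])
            continue
        if cid not in proposals:
            proposals[cid] = rng.dirichlet(bias_concentration * props * n_clusters)
        labels[bc] = int(rng.choice(n_clusters, p=proposals[cid]))

    truth = {
        "cluster_props": props.tolist(),
        "biased_clonotypes": sorted(map(str, biased)),
        "forced_cluster": {str(k): int(v) for k, v in forced_cluster.items()},
        "proposals": {str(k): v.tolist() for k, v in proposals.items()},
    }
    return labels, truth


def generate_regulon_runs(
    n_runs: int = 100,
    stable_tfs=tuple("TF_STABLE_%d" % i for i in range(1, 11)),
    decoy_tfs=tuple("TF_DECOY_%d" % i for i in range(1, 11)),
    n_core_targets: int = 8,
    n_noise_targets: int = 6,
    stable_occ: float = 0.9,
    target_occ: float = 0.95,
    decoy_occ: float = 0.5,
    gene_universe=None,
    seed: int = 0,
):
    """Simulate repeated stochastic regulon inference.

    Stable TFs appear in each run with probability ``stable_occ`` carrying
    their core targets with probability ``target_occ`` plus run-specific noise
    targets; decoy TFs appear at ``decoy_occ``. Returns ``(runs, truth)`` where
    ``runs`` is a list of ``{tf: set(targets)}`` maps.
    """
    rng = np.random.default_rng(seed)
    stable_tfs = list(stable_tfs)
    decoy_tfs = list(decoy_tfs)
    for occ in (stable_occ, target_occ, decoy_occ):
        if not 0 < occ < 1:
            raise ValueError("occurrence probabilities must lie in (0, 1)")
    if gene_universe is None:
        gene_universe = [f"G{i:04d}" for i in range(400)]
    core = {}
    pool = list(gene_universe)
    idx = rng.permutation(len(pool))
    k = 0
    for tf in stable_tfs + decoy_tfs:
        core[tf] = {pool[idx[k + j]] for j in range(n_core_targets)}
        k += n_core_targets
    runs = []
    for _ in range(n_runs):
        run = {}
        for tf in stable_tfs:
            if rng.random() < stable_occ:
                targets = {g for g in core[tf] if rng.random() < target_occ}
                noise = rng.choice(len(pool), size=n_noise_targets, replace=False)
                targets |= {pool[i] for i in noise}
                run[tf] = targets or set(core[tf])
        for tf in decoy_tfs:
            if rng.random() < decoy_occ:
                targets = {g for g in core[tf] if rng.random() < target_occ}
                run[tf] = targets or set(core[tf])
        runs.append(run)
    truth = {
        "stable_tfs": stable_tfs,
        "decoy_tfs": decoy_tfs,
        "core_targets": {tf: sorted(core[tf]) for tf in stable_tfs + decoy_tfs},
        "stable_occ": stable_occ,
        "target_occ": target_occ,
        "decoy_occ": decoy_occ,
    }
    return runs, truth


def generate_pseudotime(
    barcodes,
    group_of: dict,
    effects: dict | None = None,
    noise_sd: float = 1.0,
    effect_correlation: float = 1.0,
    base: float = 5.0,
    trajectories=("TCR", "cytokine"),
    seed: int = 0,
):
    """Per-cell pseudotime on two trajectories with planted group shifts.

    ``effects`` maps group id -> shift applied on the first trajectory; shifts
    on the second trajectory are ``rho * e + sqrt(1 - rho^2) * eps`` with
    ``rho = effect_correlation`` and ``eps`` drawn from the empirical spread of
    the supplied effects, so ``rho = 1`` reproduces the shifts exactly.
    Returns ``(table, truth)`` with ``table`` a barcode x trajectory DataFrame.
    """
    rng = np.random.default_rng(seed)
    barcodes = list(barcodes)
    effects = dict(effects or {})
    groups = sorted({group_of[bc] for bc in barcodes if bc in group_of}, key=str)
    e1 = {g: float(effects.get(g, 0.0)) for g in groups}
    spread = float(np.std(list(e1.values()))) or 1.0
    rho = effect_correlation
    e2 = {
        g: rho * e1[g] + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(0.0, spread)
        for g in groups
    }
    effect_maps = {trajectories[0]: e1, trajectories[1]: e2}
    data = {}
    for traj in trajectories:
        em = effect_maps[traj]
        shifts = np.array([em.get(group_of.get(bc), 0.0) for bc in barcodes])
        data[traj] = base + shifts + rng.normal(0.0, noise_sd, size=len(barcodes))
    table = pd.DataFrame(data, index=barcodes)
    truth = {t: {str(k): float(v) for k, v in effect_maps[t].items()} for t in trajectories}
    return table, truth


def generate_expression(
    barcodes,
    coreceptor_labels: dict | None = None,
    mode: str = "gene",
    regulon_gene_sets: dict | None = None,
    activity_shifts: dict | None = None,
    n_genes: int = 200,
    seed: int = 0,
):
    """Expression matrix honoring coreceptor thresholds and activity shifts.

    Coreceptor channels are drawn so that the stated assignment rules recover
    each cell's target label exactly. ``activity_shifts`` maps TF ->
    ``(shifted_barcodes, boost_probability)``: in shifted cells, each target
    gene of that TF's set is boosted to the top of the expression ranking with
    the given probability, raising the recovery-curve score by a controlled
    margin. Background expression is lognormal. Returns a cells x genes
    DataFrame including the coreceptor channels as columns.
    """
    rng = np.random.default_rng(seed)
    barcodes = list(barcodes)
    n_cells = len(barcodes)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    values = rng.lognormal(0.0, 1.0, size=(n_cells, n_genes))
    df = pd.DataFrame(values, index=barcodes, columns=genes)

    if regulon_gene_sets:
        top = float(values.max())
        for tf, (shifted, boost_p) in (activity_shifts or {}).items():
            targets = [g for g in regulon_gene_sets[tf] if g in df.columns]
            shifted = set(shifted)
            rows = [i for i, bc in enumerate(barcodes) if bc in shifted]
            for i in rows:
                mask = rng.random(len(targets)) < boost_p
                for g, m in zip(targets, mask):
                    if m:
                        df.iat[i, df.columns.get_loc(g)] = top + 1.0 + rng.random()

    if coreceptor_labels is not None:
        if mode == "gene":
            cd8a = np.zeros(n_cells)
            cd8b = np.zeros(n_cells)
            cd4 = np.zeros(n_cells)
            for i, bc in enumerate(barcodes):
                label = coreceptor_labels[bc]
                if label == "CD8+":
                    cd8a[i] = rng.uniform(0.5, 3.0)
                    if rng.random() < 0.5:
                        cd8b[i] = rng.uniform(0.5, 3.0)
                elif label == "CD4+":
                    cd4[i] = rng.uniform(0.5, 3.0)
                elif label != "DN":
                    raise ValueError(f"unknown coreceptor label {label!r}")
            df["CD8A"], df["CD8B"], df["CD4"] = cd8a, cd8b, cd4
        elif mode == "protein":
            cd8 = np.zeros(n_cells)
            cd4 = np.zeros(n_cells)
            for i, bc in enumerate(barcodes):
                label = coreceptor_labels[bc]
                if label == "CD8+":
                    cd8[i] = rng.uniform(0.4, 2.0)
                    cd4[i] = rng.uniform(0.0, 1.0)
                elif label == "CD4+":
                    cd8[i] = rng.uniform(0.0, 0.15)
                    cd4[i] = rng.uniform(3.0, 5.0)
                else:
                    cd8[i] = rng.uniform(0.0, 0.15)
                    cd4[i] = rng.uniform(0.0, 2.0)
            df["CD8"], df["CD4"] = cd8, cd4
        else:
            raise ValueError("mode must be 'gene' or 'protein'")
    return df
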