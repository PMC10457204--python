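# clonolink

Clonotype calling and clonotype–function integration for paired single-cell
TCR sequencing, built around the repertoire structure of human MAIT
(mucosal-associated invariant T) cells.

MAIT cells carry a semi-invariant TCRα chain (TRAV1-2 joined to
TRAJ33/TRAJ12/TRAJ20 with a 12-amino-acid CDR3α) paired with diverse β chains.
Studies of such repertoires need to answer questions like: how clonal is the
repertoire and how diverse (Shannon index over clone sizes)? Are clonotypes
shared between matched tissues (blood vs liver) and between donors (public vs
private)? Are the cells of a clonotype distributed nonrandomly across
transcriptional clusters? Do clonal identity and TRBV usage predict a cell's
position along activation (pseudotime) trajectories? Which transcription-factor
regulons are stably inferred across repeated stochastic network-inference runs,
and how does their per-cell activity differ between stimulation conditions?

`clonolink` implements this tool chain:

- **contig_io** — parse 10x `filtered_contig_annotations.csv` tables, keep
  high-confidence/full-length/productive TRA/TRB contigs, assemble per-barcode
  chain sets, discard TCR-defined doublets (2α+2β, or >2 of either chain), and
  gate MAIT vs conventional-memory populations.
- **clonotype_calling** — six clonotype definitions (nucleotide and functional
  amino-acid level × αβ / α-only / β-only). Functional calling is
  dropout-tolerant: a cell belongs to a clonotype if every chain it *does*
  carry matches the clonotype's chain set. Clonotypes are numbered by size
  (ties randomly ordered, seeded) and ranked with competition ranking.
- **repertoire_metrics** — Shannon diversity `H = −Σ pᵢ ln pᵢ`, clonality
  curves, chain-pairing promiscuity, TRAJ×TRBV pairing tables, segment usage,
  cross-tissue sharing and shared-clonotype frequency correlation, publicness
  spectra across donors, equal-depth downsampled comparisons, TCR capture rate.
- **cluster_association** — exact multinomial goodness-of-fit test of a
  clonotype's cluster distribution against sample-wide cluster proportions,
  with full enumeration when the outcome count `C(n+k−1, k−1) < 10⁶` and
  Monte-Carlo sampling (`ntrial = min(10·events, 10⁸)`, add-one p estimator)
  otherwise; Bonferroni adjustment per donor-sample family.
- **regulon_consensus** — high-confidence regulons from repeated stochastic
  GRN-inference runs (TF occurrence strictly >80% of runs, ≥5 targets each
  present in strictly >80% of the TF's runs), gene×TF occurrence matrices,
  AUCell-style recovery-curve activity scores, rank-sum differential activity.
- **function_link** — CD8/CD4/DN coreceptor assignment from gene or protein
  expression, Kruskal–Wallis pseudotime association for clonotypes/TRBV groups,
  cross-trajectory correlation of group effects, clone-size–pseudotime
  correlation, differential gene-importance rank ratios.
- **synthetic_data** — generators for all of the above inputs with recorded
  ground truth (planted clonal partitions, tissue overlap, cluster bias,
  pseudotime shifts, stable regulons), used by the test suite.

## Worked example

```python
from clonolink import synthetic_data as sd, contig_io, clonotype_calling as cc
from clonolink import repertoire_metrics as rm

cfg = sd.RepertoireConfig(seed=1, donors=2, cells_per_sample=500,
                          dropout=0.0, doublet_rate=0.0, capture_rate=1.0)
contigs, meta, truth = sd.generate_repertoire(cfg)
contigs.to_csv("contigs.csv", index=False)

records = contig_io.filter_contigs(contig_io.read_contig_table("contigs.csv"))
cells, n_doublets = contig_io.assemble_cells(records, meta.set_index("barcode"))
mait = contig_io.gate_cells(cells, "MAIT")

table = cc.number_and_rank(cc.call_functional_clonotypes(mait, "ab"), seed=17)
print(len(mait), "MAIT cells,", len(table.sizes), "functional clonotypes")
print("Shannon H =", round(rm.shannon_index(table.sizes.values()), 3))

blood = cc.call_nucleotide_clonotypes([c for c in mait if c.tissue == "blood"], "ab")
liver = cc.call_nucleotide_clonotypes([c for c in mait if c.tissue == "liver"], "ab")
share = rm.cross_sample_sharing(blood, liver)
print("blood-liver sharing: %.1f%% / %.1f%%" % (share.pct_shared_a, share.pct_shared_b))
```

prints

```
2000 MAIT cells, 265 functional clonotypes
Shannon H = 4.936
blood-liver sharing: 66.6% / 68.2%
```

2,000 gated cells fall into 265 functional clonotypes (the generator plants
150 clones per donor, some never sampled, and public α chains merge a few
across donors), the Shannon index of 4.94 nats reflects an oligoclonal size
distribution (a uniform one would give ln 265 ≈ 5.6), and roughly two thirds
of cells in each tissue belong to a clonotype also seen in the donor's other
tissue — close to the planted tissue overlap of 0.7, minus the shared clones
that this modest sample misses.

The same pipeline is scriptable from the shell:

```sh
clonolink simulate --seed 1 --donors 2 --cells-per-sample 500 --out sim/
clonolink ingest --contigs sim/contigs.csv --meta sim/meta.csv --population MAIT --out cells.json
clonolink clonotypes --cells cells.json --level fn-ab --seed 17 --out clonotypes.csv
clonolink metrics --clonotypes clonotypes.csv --metric shannon
```

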