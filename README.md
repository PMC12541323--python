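# sh2swap

Dry-lab machinery for high-throughput **domain-swap fitness screens** of
modular kinases, modelled on sort-seq screens of Bruton's tyrosine kinase
(BTK) in which the SH2 domain (residues 281–362) or the C-terminal kinase
helix (αI) is replaced by hundreds of homologous, ancestral, or control
sequences. The package covers everything between a sequence database and a
fitness table:

* **Library curation** (`domain_select`) — deduplication, identity-band
  filtering against the human reference, progressive per-paralog selection,
  and point-substitution controls at the phosphotyrosine-binding arginine
  (R307→K above 60 % identity, R307→stop above 95 %), assembled into
  auditable manifests.
* **Ancestral sequence reconstruction** (`asr`) — maximum-likelihood
  reconstruction on a fixed tree under an empirical 20-state model (JTT by
  default), with both **marginal** (per-node posterior) and **joint**
  (Pupko-style max-product) modes and two gap strategies (prune every
  gapped column, or treat gaps as missing data).
* **Oligo-pool design** (`oligo_design`) — codon-preserving reverse
  translation (reference codons wherever the residue matches; random
  synonymous codons elsewhere), BsaI-site (GGTCTC/GAGACC) exclusion inside
  the variable region, four synonymous realizations per protein,
  Golden-Gate handles, background barcodes, and padding to a uniform 300-nt
  synthesis length.
* **Quantification** (`quantify`) — alignment-free k-mer read assignment,
  dual demultiplexing (variant + 3-nt background barcode), a 50-read input
  filter, and the sort-seq fitness score

  ```
  fitness_i = log10(SortCount_i / InputCount_i)
            - mean_wt[ log10(SortCount / InputCount) ]
  ```

  normalized so synonymous wild-type sequences average exactly 0 in every
  replicate, plus replicate SEM, background differences with propagated
  standard errors, and Pearson replicate-agreement QC.
* **Synthetic experiments** (`synthetic_data`, `study`) — fully seeded
  generators for domain sets with controlled identity, trees with sequences
  evolved under the same substitution model, and complete sort-seq count
  tables (multinomial sampling with selection weight 10^g), so every stage
  is testable against known ground truth.

## Worked example

Simulate a screen of 300 variants (20 wild-type synonyms, 10 stop-class
variants at g = −1.5, one gain-of-function variant at g = +0.23) at 10⁶
reads per sample across 4 replicates, then score it:

```python
from sh2swap import study

merged = study.recovery_experiment(seed=1)
gain = merged[merged["class"] == "gain"].iloc[0]
print(f"gain variant: {gain['mean']:.3f} +/- {gain['sem']:.3f}")
rmse = ((merged["mean"] - merged["g"]) ** 2).mean() ** 0.5
print(f"recovery RMSE: {rmse:.4f}")
```

prints

```
gain variant: 0.230 +/- 0.006
recovery RMSE: 0.0079
```

i.e. the planted +0.23 enrichment is recovered within the replicate SEM and
all 300 planted values are recovered with an RMSE well below 0.05 log10
units. The same pipeline is exposed on the command line:

```bash
sh2swap simulate --seed 1 --out-dir run/
sh2swap score --counts run/counts.tsv --wt-prefix wt_syn --out-dir run/
sh2swap qc --scores run/scores.tsv --out-dir run/
```

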