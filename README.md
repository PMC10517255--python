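# uoxcoopt

Analyses for studying the evolutionary co-option of uricase (urate oxidase,
Uox) in reptiles: although uricotelic vertebrates no longer degrade uric
acid in the liver, their *Uox* gene is conserved, cysteine-enriched, and
encodes an enzyme with drastically reduced turnover. This package implements
the three bespoke computations behind that story as a tested Python library
with a small CLI:

* **`uoxcoopt.orthocomp`** — differential amino-acid composition scanning
  across vertebrate orthogroups. Orthogroups are filtered to single-copy
  genes present in ≥ 90% of species; per-sequence content of each amino acid
  is computed as a fraction of counted length; each (orthogroup × amino
  acid) is tested between two clades with a two-sided Welch *t*-test and
  classified volcano-style (`increased` / `decreased` / `ns`) at a raw
  *p*-value cutoff of 1e-16 and a log₂ fold-change cutoff of ±1.
* **`uoxcoopt.ancgain`** — per-branch ancestral cysteine gain/loss
  reconstruction on a rooted phylogeny. Alignment columns are recoded as
  binary presence/absence of a target residue and reconstructed under
  parsimony (`mpr`, `mpr_acctran`) or a two-state continuous-time Markov
  chain (`ml` joint reconstruction, `bayes` marginal highest-posterior
  states); branch events are summed into gains, losses, and net enrichment
  (gain − loss).
* **`uoxcoopt.kinetics`** — uricase catalysis as a sequential chain
  UA ⇌ UA²⁻ ⇌ PIU ⇌ HIU with rate constants k₁…k₃ and k₋₁…k₋₃, solved
  exactly; Beer–Lambert spectral synthesis; SVD of time-resolved spectra
  with isolated-wavelength selection; single-wavelength chain fitting;
  Michaelis–Menten estimation (v = V·S/(K_M + S), k_cat = V/[E]); and the
  FOX-assay linear standard curve for H₂O₂ quantification at 595 nm.
* **`uoxcoopt.synthetic`** — seeded generators for every input above, with
  recorded ground truth for parameter-recovery testing.

## Worked example

Recover the kinetic parameters of the chicken enzyme from a synthetic
triplicate initial-rate experiment (2–140 µM urate, 2% noise):

```python
import numpy as np
from uoxcoopt import kinetics, synthetic

data, truth = synthetic.gen_mm_dataset(km=12.5, kcat=0.03, enzyme_conc=0.5,
                                       noise_cv=0.02, replicates=3, seed=1)
fit = kinetics.fit_michaelis_menten(data.substrate_uM, data.rate_uM_per_s,
                                    enzyme_conc=0.5)
print(f"K_M = {fit.km:.2f} uM, k_cat = {fit.kcat:.4f} /s")
```

prints

```
K_M = 12.35 uM, k_cat = 0.0299 /s
```

i.e. the planted K_M of 12.5 µM and turnover number of 0.03 s⁻¹ are
recovered within a few percent from noisy rates. The same round trip on the
zebrafish parameters (K_M 11 µM, k_cat 3.95 s⁻¹) shows the > 100-fold
turnover gap between the two enzymes.

The same flow from the shell:

```bash
uoxcoopt generate mm --seed 1 --out demo
uoxcoopt kinetics fit-mm --rates demo/rates.csv --enzyme-conc 0.5 --out demo/fit.json
```

For the composition scan and the ancestral reconstruction:

```bash
uoxcoopt orthocomp --fasta seqs.fasta --membership membership.tsv \
    --clades clades.tsv --pair Sauropsida,Mammalia --out scan/
uoxcoopt ancgain --tree tree.nwk --alignment aln.fasta --residue C \
    --method bayes --out anc/
```

`orthocomp` writes the full differential table (one row per orthogroup ×
amino acid: means, log₂ fold change, Welch *p*-value, volcano class) plus a
per-amino-acid summary of increased/decreased counts; `ancgain` writes the
per-branch gain/loss/net table and, for `bayes`, per-node posterior
probabilities. `uoxcoopt.orthocomp.load_orthodb_flat` is the entry point for
running the scan on OrthoDB-style flat files at full database scale.

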