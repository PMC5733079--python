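# lohsim

Modelling and analysis of how **resting diploid yeast cultures keep
yielding recessive drug-resistant mutants** when a cytidine deaminase
(APOBEC-family, e.g. PmCDA1) is expressed — even though the cells have
stopped dividing and their genome-wide mutation loads stay constant.

The package is for researchers studying APOBEC mutagenesis,
loss-of-heterozygosity (LOH), and mutation-cluster (kataegis) formation
who want a tested, reusable implementation of:

* the **hypermutable-fraction frequency model** of recessive mutant
  recovery in haploids vs diploids,
* a **forward culture simulator** of growth-phase mutagenesis,
  resting-phase LOH ("return-to-growth" recombination) and late meiosis,
* a **synthetic diploid-genome generator** producing clone VCFs with
  APOBEC-signature heterozygous SNVs, LOH tracts and break-associated
  mutation clusters with reciprocal C→T/G→A polarity,
* the **clone-analysis pipeline**: strand-bias (FS) and genome-mask
  filtering, zygosity profiles, single-SNV LOH calling on the reporter
  arm of chromosome V, breakpoint-interval estimation, ploidy inference
  and day-by-day mutation-load statistics,
* the **chromosome-V marker assay classifier** mapping Ade/Ura/Can
  phenotypes and CAN1 genotypes to event classes (point mutation, gene
  conversion, interval crossovers, chromosome loss, haploidization).

## The model

A fraction *f* of cells is transiently hypermutable: its per-copy
reporter inactivation rate is μ_h (default 10⁻³) versus μ (default 10⁻⁶)
in the rest of the culture. A recessive reporter (CAN1) yields resistant
diploid clones by two routes:

* **coincidence** — independent hits in both homologs:
  `F_c(f) = f·μ_h² + (1−f)·μ²`
* **mutation–segregation** — one heterozygous hit made homozygous by an
  LOH event at per-cell frequency *r*:
  `F_s(f) = [f·μ_h + (1−f)·μ] · r`

Haploids are predicted at the linear mixture `f·μ_h + (1−f)·μ` but
observed at μ, because hypermutable haploids exceed the tolerable
genome-wide load and die; hypermutable diploids survive (their lethal
hits stay heterozygous) and carry hundreds to thousands of passenger
C→T/G→A SNVs. Resting cultures commit to meiotic-like recombination, so
*r* rises by orders of magnitude during starvation — which is why the
recovered mutant frequency keeps climbing for days after growth stops
while the load per genome does not.

## Worked example

```python
from lohsim.model import ModelParams, coincidence_frequency, segregation_frequency
from lohsim.simulate import SimConfig, run_experiment

p = ModelParams()                       # mu=1e-6, mu_h=1e-3, r=3e-4
coincidence_frequency(p, 0.0)           # 1e-12
coincidence_frequency(p, 0.01)          # 1.000099e-08  (a 4-orders rise)
segregation_frequency(p, 0.01)          # 3.297e-09

run_experiment(SimConfig(seed=1)).table
```

prints the daily plating table of one simulated diploid culture:

```
 day  n_plated_selective  n_resistant  n_plated_permissive  n_viable  frequency
   0            10000000            0                 1000      1000          0
   1          1000000000           45                 1000      1000    4.5e-08
   2          1000000000           84                 1000      1000    8.4e-08
   3          1000000000          110                 1000      1000    1.1e-07
   4          1000000000         1073                 1000      1000   1.07e-06
   5          1000000000         2056                 1000      1000   2.06e-06
   6          1000000000         5194                 1000      1000   5.19e-06
```

No resistant colonies on day 0 (a recessive reporter needs two events),
a day-1 frequency set by coincident double hits in the hypermutable
fraction, and then a roughly hundredfold climb through day 6 driven
entirely by resting-phase LOH acting on the standing pool of
heterozygous reporter hits — while `mean_genome_load()` stays flat.

The same machinery is scriptable from the shell:

```bash
lohsim model-curves --out curves.tsv
lohsim simulate --seed 1 --out run/
lohsim synth --n-clones 3 --n-snvs 2000 --loh-breakpoint 90000 --seed 2 --out clones/
lohsim call clones/*.vcf
lohsim run --seed 1 --out full_run/        # simulate → synth → call → classify + manifest
```

## Layout

| module | contents |
| --- | --- |
| `lohsim.model` | frequency model (`ModelParams`, mechanism curves) |
| `lohsim.simulate` | cohort-based culture simulator, plating, clone archive |
| `lohsim.genomes` | `Variant`/`CloneGenome`, marker map, synthetic references |
| `lohsim.synth` | deamination spikes, LOH tracts, break clusters, event clones |
| `lohsim.pipeline` | filtering, zygosity, LOH/breakpoint calling, load statistics |
| `lohsim.events` | marker phenotypes, event classes, proportions, box statistics |
| `lohsim.vcfio` | clone VCF read/write, BED masks, metadata tables |
| `lohsim.cli` | `lohsim` command-line interface and run manifests |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and their rationale, and known limitations.
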