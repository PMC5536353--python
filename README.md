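# rdnamap

Input-normalized occupancy mapping, factor-release kinetics and
psoralen densitometry for the mouse ribosomal RNA gene repeat.

## What problem this solves

The ~200 copies of the mouse 47S rRNA gene sit in a ~45.3 kb tandem
repeat (reference BK000964v3). Because the repeat is present in hundreds
of copies, ChIP-Seq reaches extreme depth on it — but raw coverage is
strongly (and reproducibly) distorted by the underlying sequence, and the
repeat's functional unit straddles the ends of the conventional GenBank
numbering. `rdnamap` implements the analysis chain used to turn aligned
read positions on a single-copy rDNA "extra chromosome" into quantities
of biological interest:

* **Coordinates** — the repeat is modeled as a circle with a displaced
  numbering origin (the EcoRI site at native 30,493 becomes position 1,
  putting the 47S initiation site at 14,815), with lossless conversion
  between native, displaced and TSS-relative frames and support for
  intervals that wrap the origin (e.g. the 47S promoter amplicon
  45133–40).
* **Enrichment tracks** — reads are extended to the estimated fragment
  length (100 bp), per-base coverage *j(n)* is smoothed with a 25 bp
  centered mean *J(n) = (1/25) Σ j*, scaled to reads per million, and the
  ChIP track is divided by the matched input track,
  *J*<sub>norm</sub> = *J*<sub>ChIP</sub>/*J*<sub>input</sub>,
  which cancels the shared sequence bias.
* **Release kinetics** — the initiation factor Rrn3 leaves the elongating
  polymerase stochastically, so its enrichment decays as
  *A*·exp(−*d*/*L*<sub>c</sub>) + *B* downstream of +1; the fitted decay
  length converts to a temporal half-life
  *t*<sub>½</sub> = *L*<sub>c</sub>·ln 2/*v* at elongation rate
  *v* (60 nt/s).
* **Region statistics** — per-feature means/maxima, signal fractions,
  windowed peak calls relative to anchors (the stalled polymerase 24 bp
  downstream of the Spacer Promoter +1), and between-feature ratios
  (histone H3 over the gene body relative to the intergenic spacer).
* **Psoralen gels** — the active rDNA fraction from a 1-D lane trace by a
  two-Gaussian fit over a linear baseline; area share of the low-mobility
  band = active fraction.
* **Synthetic data** — a generator that emits all of the above inputs
  (reads, features, gel traces, repeat sequence) from scenarios with
  known ground truth, including an active/inactive repeat mixture and a
  shared multiplicative coverage-bias field.

## Worked example

```python
import rdnamap as r
from rdnamap.coverage import enrichment_pipeline
from rdnamap.simulate import build_mef_scenario, sample_reads

sc = build_mef_scenario("WT", seed=42)          # half-life 15 s ground truth
chip = sample_reads(sc, "Rrn3", 200_000, seed=43)
inp = sample_reads(sc, "input", 200_000, seed=44)
enr = enrichment_pipeline(chip, inp, sc.repeat_length)
fit = r.fit_exponential_decay(enr, tss=sc.tss)
est = r.halflife_from_decay(fit, elongation_rate=60.0)
print(f"decay length Lc = {fit.decay_length:.1f} bp")
print(f"half-life       = {est.half_life:.2f} s")
```

prints

```
decay length Lc = 1259.0 bp
half-life       = 14.54 s
```

i.e. from 200,000 simulated reads the pipeline recovers the scenario's
15 s release half-life to within ~3%. The analogous gel round trip:

```python
from rdnamap.simulate import simulate_gel_trace, gel_noise_sd
trace = simulate_gel_trace(0.64, noise_sd=gel_noise_sd(0.64), seed=42)
gfit = r.fit_two_gaussians(trace)
frac = r.active_fraction(gfit, trace, n_bootstrap=200, seed=1)
print(f"active fraction = {100*frac.value:.1f}% +/- {100*frac.se:.1f}%")
# active fraction = 63.7% +/- 0.3%
```

A command-line interface mirrors the library
(`rdnamap simulate|coverage|kinetics|stats|gel|run-all`); e.g.

```sh
rdnamap run-all --preset WT --depth 200000 --seed 42 --outdir demo/
```

simulates a wild-type dataset, builds enrichment bedGraphs for every
factor, fits the release kinetics, calls the Spacer Promoter peak and
quantifies the gel trace, writing a `report.json` with full parameter
provenance. Identical config and seed give byte-identical outputs.

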