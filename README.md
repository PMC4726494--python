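# cobitis — karyotype stability and molecular dating of clonal hybrid loaches

European spined loaches of the *Cobitis taenia* complex form diploid and
triploid clonal hybrids (gynogens) between three sexual species, written
by their haploid genomes E (*C. elongatoides*), T (*C. taenia*) and N
(*C. tanaitica*).  Two questions drive the analysis this package
implements: do clonally transmitted karyotypes stay exactly additive —
each hybrid's chromosome-morphology counts equal to the sum of its
parental haploid complements, with GISH signal cleanly sorting every
chromosome into a parental set — and over how much absolute time has that
stability held?  The second question is a dating problem: the age of the
oldest clonal mitochondrial lineage and the speciation times of the
parental species, estimated on relative scales and converted to years
through one shared outgroup calibration.

The package provides, as a tested library under `src/cobitis/` with
narrative drivers under `analysis/`:

* **karyotype** — additive karyotype arithmetic over the four Levan
  categories (m/sm/st/a) and a two-channel GISH ratio classifier with an
  explicit ambiguity zone;
* **cohort** — the locality-level study-design table (individuals,
  metaphases, GISH experiments per biotype and clone age class), with all
  totals recomputed;
* **coalescent** — θ and TMRCA estimation for a clonal matriline under
  the infinite-sites Kingman coalescent by Griffiths–Tavaré sequential
  importance sampling: likelihood curves L(θ) from common random
  histories, profile maximization, and a weighted TMRCA posterior in
  units of N_f generations (θ = 2N_f μ);
* **chronogram** — penalized-likelihood dating (Poisson branch
  likelihood minus λ × rate roughness), leave-one-tip-out
  cross-validation of λ, and lineage-averaged substitution rates;
* **msc** — a multispecies-coalescent MCMC for the fixed species tree
  ((T,N),E): divergence times τ_TN < τ_TNE in substitutions/site and five
  θ = 4N_e μ parameters, JC69 likelihoods, per-locus rate scalars from
  ingroup–outgroup distances;
* **calib** — the unit chain t = TMRCA·N_f·g with N_f = θ/(2μ_gen) and
  τ_abs = τ/τ_outgroup × outgroup age;
* **simulate** — generators with known truth for every input above;
* **cli** — a `cobitis` command-line tool wrapping all stages.

## Worked example

Dating a synthetic clonal clade end to end (the numbers below are the
script's actual output for this seed):

```bash
$ python analysis/03_clone_age.py --seed 7
simulated clade: n=30, θ=1.156, S=3 segregating sites, true age 0.158 MYA
ML θ̂ = 0.696 (2-log-unit support 0.151–1.902)
TMRCA 2.37 coalescent units (95% 0.93–4.80), weight ESS 721
clone age (plug-in θ̂):   0.111 MYA (95% 0.044–0.226)
clone age (θ propagated): 0.118 MYA (95% 0.032–0.295)
truth 0.158 MYA inside the propagated interval
```

A clade of 30 sampled haplotypes carrying 3 segregating sites is
generated at θ = 1.156 with a recorded true age.  The θ profile peaks at
0.696; the TMRCA posterior (in coalescent units of N_f generations) is
converted to years via N_f = θ/(2μ_gen) with μ_gen from a rate of 0.0065
substitutions/site/MYA, locus length 1140 and a 2-year generation time.
The plug-in interval conditions on θ̂; the propagated interval folds in θ
uncertainty and covers the truth here.

The other drivers follow the same pattern: `01` verifies that all nine
published karyotype columns are exactly additive (EN 2n = 50, ET 2n = 49,
EET 3n = 74, ETT 3n = 73, EEN/ENN 3n = 75) and that the GISH classifier
recovers the 25 + 25 parental sets of an EN metaphase; `02` recomputes the
cohort sums (49 hybrid individuals, 299 metaphases); `04` selects the
smoothing value by cross-validation and dates a clock phylogram; `05`
runs the MSC sampler against known (τ, θ); `06` assembles the absolute
ages.  The same stages are available as `cobitis` subcommands
(`cobitis karyotype compose --comp EEN`, `cobitis pipeline --config ...`).

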