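# faoclassify

Oxidase or dehydrogenase? Tools for resolving the physiological electron
acceptor of flavoprotein amine oxidoreductases (FAOs).

FAO-family enzymes oxidize C–N bonds using an FAD cofactor and must then
reoxidize the reduced flavin (FADH₂). The classical assumption is that O₂
is the acceptor (oxidase activity, producing H₂O₂), but many bacterial
FAOs instead transfer the two electrons stepwise to a cytochrome *c*
(CytC) encoded adjacent to them in the genome — they are dehydrogenases.
`faoclassify` implements the full analysis chain that makes this call:

* **Kinetics** — mass-action simulation of flavin reoxidation by O₂
  (one irreversible bimolecular step) or CytC (two reversible
  one-electron transfers through the semiquinone), with Beer–Lambert
  observables at 450 nm (flavin) and 550 nm (heme);
* **Trace fitting** — least-squares fits of stopped-flow traces to
  `Y = ΔA·e^(−k_obs·t) + A_∞` or the two-phase sum
  `Y = ΔA₁·e^(−k_obs1·t) + ΔA₂·e^(−k_obs2·t) + A_∞`, and linear
  regression of k_obs against oxidant concentration whose slope is the
  bimolecular constant k_ox (M⁻¹s⁻¹);
* **Classification** — auditable threshold rules turning
  (k_ox^O₂, k_ox1^CytC, k_ox2^CytC) into a verdict: dehydrogenase,
  oxidase, dual, or indeterminate;
* **Genome screen** — detection of the two dehydrogenase signposts
  (twin-arginine TAT export signal on the FAO; adjacent or fused CytC
  gene, recognized by CXXCH heme motifs), assigning each FAO locus one
  of four operon categories (black / blue / green / red), plus
  >98%-identity sequence deduplication;
* **Ancestral reconstruction** — equal-rates Mk model maximum-likelihood
  reconstruction of operon categories on a rooted phylogeny, with
  marginal node probabilities and counts of independent category
  origins;
* **Synthetic data** — seeded generators for traces, annotated genomes
  with planted operons, and character-mapped Yule trees, so every stage
  is testable against known truth.

## Worked example

Recover the CytC rate constants of a fast dehydrogenase from simulated
stopped-flow data, then classify it:

```python
from faoclassify import KineticScheme, RateConstantSet, classify
from faoclassify.pipeline import RunConfig, run_kinetics
from faoclassify.synth_data import gen_stopped_flow_dataset

# two-step electron-transfer scheme, k_ox1 = 2.8e6, k_ox2 = 3.7e5 M^-1 s^-1
scheme = KineticScheme(k1f=2.8e6, k2f=3.7e5, K1=1e6, K2=1e6)
traces, manifest = gen_stopped_flow_dataset(
    scheme, 1e-6, [200e-6, 400e-6, 600e-6, 800e-6],
    sigma=0.0, seed=0, oxidant="cytc")
manifest["enzyme"] = "P_taiwanensis_like"
manifest["n_phases"] = 2
table, _ = run_kinetics(manifest, RunConfig(),
                        traces={t.label: t for t in traces})
print(table.to_string(index=False))

call = classify(RateConstantSet("P_taiwanensis_like", k_ox_o2=6.6e3,
                                k_ox1_cytc=float(table.k_ox1_cytc[0]),
                                k_ox2_cytc=float(table.k_ox2_cytc[0])))
print(call.category, call.rationale)
```

prints

```
            enzyme  k_ox_o2   k_ox1_cytc    k_ox2_cytc
P_taiwanensis_like      NaN 2.800015e+06 370000.753791
dehydrogenase k_ox1_CytC/k_ox_O2 = 424 >= 100: CytC strongly preferred
```

The biexponential fits of the four noiseless 550-nm traces recover the
generating constants (2.8×10⁶ and 3.7×10⁵ M⁻¹s⁻¹) to ~1e-5 relative as
the fast- and slow-phase k_obs slopes; paired with a measured O₂
constant of 6.6×10³ M⁻¹s⁻¹ the CytC preference ratio is 424, far above
the dehydrogenase threshold of 100.

The same operations are available from the shell:

```sh
faoclassify synth operons --seed 1 --out genomes.gb   # planted operons
faoclassify scan genomes.gb                           # -> category table
faoclassify synth tree --n-tips 32 --seed 1 --out-prefix t
faoclassify ancestral t.nwk t_tips.csv                # Mk reconstruction
faoclassify replay --seed 1 --out-dir replay_out      # full pipeline
```

## Layout

```
src/faoclassify/
  kinetic_core.py     mechanism simulation, spectra, equilibria
  trace_fit.py        exponential fits, phase selection, k_obs regression
  oxidant_classify.py preference rules
  reference_data.py   published rate-constant tables
  signpost_scan.py    TAT/Sec/CXXCH detection, operon categories, dedupe
  ancestral_mk.py     Mk likelihood, marginals, transition counts
  synth_data.py       seeded generators (traces, genomes, trees)
  pipeline.py         batch orchestration, run configs
  cli.py              `faoclassify` command
```
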