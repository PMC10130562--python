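# irmsim

Quantitative-genetics simulation of insecticide resistance management (IRM)
for public-health vector control.

Malaria control leans on a small armory of insecticides deployed as
long-lasting insecticidal nets or indoor residual spraying, and resistance
in *Anopheles* mosquitoes is usually polygenic — many loci of small effect
— rather than the single-locus trait most IRM models assume. `irmsim`
models resistance to each insecticide as a quantitative trait: the
population-mean Polygenic Resistance Score z̄ maps to diagnostic-dose
bioassay survival through a Hill curve (K_max = 1, z50 = 900, so z̄ = 100 ⇔
10% survival, the WHO confirmed-resistance level), selection follows the
sex-specific breeder's equation R = βh²x(1+m)/2, fitness costs erode
resistance by ψR per generation wherever the insecticide is not selecting,
cross resistance enters as a genetic correlation α, and an intervention
site exchanges migrants with an untreated refugia. On top of this kernel
the package implements the armory bookkeeping (withdrawal at 10% bioassay
survival, return below 8%) and four deployment strategies — sequences,
rotations, adaptive rotations, and full-dose two-insecticide mixtures —
compared by their *strategy lifespan* (generations until nothing is left
to deploy, capped at 500).

It is written for modellers and vector-control analysts who want to rerun
or extend the strategy comparisons: paired Latin-hypercube experiment
designs, win/draw/operational-win classification, β calibration, and
sensitivity analyses (PRCC, negative-binomial GLM, random-forest variable
importance).

## Worked example

The printed example parameter set (deployment interval 10, no cross
resistance, novel insecticides, h² = 0.2028686, male exposure 0.2500806,
female exposure 0.8645515, fitness cost 0.1730878, coverage 0.6885651,
dispersal 0.8844445):

```
$ irmsim simulate --strategy sequence --h2 0.2028686 --psi 0.1730878 \
    --x 0.8645515 --m 0.2500806 --coverage 0.6885651 --dispersal 0.8844445
lifespan_generations=420
terminated_by=armory-exhausted
mean_deployed_survival=0.057144
peak_survival=0.101636
```

Insecticide 1 is deployed until bioassay survival reaches 10%, is replaced
by insecticide 2, decays below the 8% return threshold while idle, is
redeployed after insecticide 2 fails, and the armory is exhausted at
generation 420 (42 yearly deployment cycles). The same parameters under
`--strategy rotation` or `--strategy mixture` run to the 500-generation
cap with both insecticides still deployable.

The same comparison at scale, on a paired Latin-hypercube design:

```
$ irmsim compare --design equal --n-lhs 500 --seed 0
== sequence vs rotation ==
                      count    percent
outcome:sequence       3253  14.786364
outcome:rotation       3244  14.745455
outcome:draw          15503  70.468182
operational:sequence   1710   7.772727
operational:rotation   1870   8.500000
operational:draw      18420  83.727273
== mixture vs both ==
                                       count    percent
outcome:draw                           13663  62.104545
outcome:mixtures-win                    7460  33.909091
outcome:sequences-lose                   652   2.963636
outcome:rotations-lose                   225   1.022727
operational:no-operational-win         14281  64.913636
operational:mixture-operational-win     6803  30.922727
operational:sequence-operational-loss    757   3.440909
operational:rotation-operational-loss    159   0.722727
```

Sequences and rotations draw in ~72% of pairings and win about equally
often otherwise, while the full-dose mixture strictly outlasts both solo
strategies in about a third of pairings and is never strictly worse than
both — the headline case for mixture formulations. `irmsim calibrate`
reproduces the β calibration (modal insecticide lifespan ~10 years at
β = 10) and `irmsim analyze` runs the PRCC/GLM/random-forest analyses on a
saved outcome table.

See `docs/methods.md` for the model equations, deployment rules, design
construction and the package's numerical choices.

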