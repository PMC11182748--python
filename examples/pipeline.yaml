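# Full synthetic analysis: a depression-like trait (MDD), four
# atherosclerotic-disease traits sharing a latent liability with it, and one
# mediating risk factor (RF); every pipeline stage enabled.
outdir: comorbigen_run
seed: 5
stages: [simulate, clean, rg, local, mixture, factor, enrichment, adjusted, mr]
simulation:
  traits:
    - {name: MDD,    h2: 0.30, n: 100000, pi: 0.1, loading: 0.25}
    - {name: CAD,    h2: 0.20, n: 100000, pi: 0.1, loading: 0.32}
    - {name: PAD,    h2: 0.18, n: 100000, pi: 0.1, loading: 0.30}
    - {name: HF,     h2: 0.15, n: 100000, pi: 0.1, loading: 0.27}
    - {name: STROKE, h2: 0.12, n: 100000, pi: 0.1, loading: 0.20}
    - {name: RF,     h2: 0.25, n: 100000, pi: 0.1, loading: 0.28}
  m_variants: 10000
  n_blocks: 100
  pi_shared: 0.05
maf: 0.05
local_pair: [MDD, CAD]
mixture_pair: [MDD, CAD]
factor_traits: [MDD, CAD, PAD, HF, STROKE]
adjust_covariates: [RF]
mr_exposure: MDD
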