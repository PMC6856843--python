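"""Compare between-study correlation structures and transforms by DIC.

Four variants are fitted to the same data: the three correlation
structures with the log transform fixed, and the independence model with
the Box-Cox transform parameter estimated.  Lower DIC is better; pD is
the effective number of parameters.
"""

import numpy as np

import threshmeta as tm

dataset, truth = tm.generate(tm.ScenarioSpec(n_studies=18, seed=99))
mcmc = tm.McmcConfig(chains=2, warmup=400, iterations=600, seed=11)

models = {
    "full correlation, log()": tm.ModelConfig(structure="full"),
    "structured corr,  log()": tm.ModelConfig(structure="structured"),
    "independence,     log()": tm.ModelConfig(structure="independence"),
    "independence,  Box-Cox ": tm.ModelConfig(
        structure="independence", transform=tm.TransformSpec(mode="estimated")),
}

rows = []
for label, model in models.items():
    fit = tm.fit(dataset, model, mcmc)
    rows.append((label, fit))

print(f"{'model':28s} {'Dbar':>7s} {'pD':>6s} {'DIC':>7s}")
best = min(fit.dic["dic"] for _, fit in rows)
for label, fit in rows:
    d = fit.dic
    flag = "  <- preferred" if d["dic"] == best else ""
    print(f"{label:28s} {d['Dbar']:7.1f} {d['pD']:6.1f} {d['dic']:7.1f}{flag}")

bc_fit = rows[-1][1]
lam = bc_fit.stacked("lambda")
print(f"\nestimated Box-Cox lambda: {np.median(lam):.2f} "
      f"(95% CrI {np.quantile(lam, 0.025):.2f}, {np.quantile(lam, 0.975):.2f})")
print("The data were generated with lambda = 0 (log-logistic results), so the")
print("extra transform parameter buys little and the DIC typically prefers the")
print("simpler log-transform model; correlation parameters likewise add")
print("complexity without improving fit when the generator has none.")
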