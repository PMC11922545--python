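"""Multivariate histograms and the group-level statistics.

Builds the trivariate histogram (regional pimo% x HIF% colored by mean ORR),
extracts the conditional ORR distribution of low-pimo/high-HIF regions,
compares it against a null section with the chi-square homogeneity test, and
demonstrates regression, ANCOVA slope comparison, and Holm adjustment.
"""

import numpy as np

import redoxmap as rm
from redoxmap.histograms import conditional_distribution, histogram, trivariate


def regional_maps(seed, subpops=None):
    kwargs = {} if subpops is None else {"subpop_spec": subpops}
    cfg = rm.GeneratorConfig(shape=(1024, 1024), seed=seed, **kwargs)
    sec = rm.generate_section(cfg)
    model = rm.fit_calibration(rm.generate_calibration_records(cfg))
    moved, (pf, pm) = rm.misregister(list(sec.ihc_images), sec.truth.transform_true,
                                     sec.truth.landmarks)
    return rm.analyze_section(sec.nadh, sec.fad, *moved, pf, pm, model,
                              rm.default_thresholds(cfg), radius_um=100.0).regional


reg = regional_maps(seed=8)
reg_null = regional_maps(seed=9, subpops=[])

edges = np.linspace(0, 1, 26)
tri = trivariate(reg.pimo_frac, reg.hif_frac, reg.orr_mean, edges, edges,
                 mask=reg.mask, z_name="ORR")
occupied = tri.base.counts > 0
print(f"trivariate histogram: {occupied.sum()} occupied bins, "
      f"z = mean regional ORR in [{np.nanmin(tri.z_mean):.2f}, {np.nanmax(tri.z_mean):.2f}]")

cond = conditional_distribution(reg, {"pimo": "low", "hif": "high"},
                                {"pimo": 0.5, "hif": 0.5}, target="orr")
centers = cond.centers[0]
mean_cond = (cond.counts_percent * centers).sum() / 100
print(f"conditional ORR (low-pimo, high-HIF regions): mean {mean_cond:.3f} "
      f"over {cond.n_total} px; percents sum to {cond.counts_percent.sum():.1f}")

h_edges = np.linspace(0, 1, 51)
h1 = histogram(reg.orr_mean, h_edges, mask=reg.mask)
h0 = histogram(reg_null.orr_mean, h_edges, mask=reg_null.mask)
res = rm.chi2_homogeneity(h1, h0)
print(f"chi2 homogeneity vs null section: chi2 = {res.chi2:.1f}, "
      f"df = {res.df}, p = {res.p:.3g}")

# regression + ANCOVA on synthetic per-section summaries (pimo% vs HIF%)
rng = np.random.default_rng(0)
x = rng.uniform(0.5, 4.0, 12)
groups = [(x, 2.8 * x + rng.normal(0, 0.8, 12)),   # steeper coupling
          (x, 1.2 * x + rng.normal(0, 0.8, 12))]   # shallower coupling
for i, (xs, ys) in enumerate(groups):
    fit = rm.linear_regression(xs, ys)
    print(f"group {i}: slope m = {fit.slope:.3f}, R^2 = {fit.r_squared:.3f}, "
          f"p_line = {fit.p_line:.4f}")
cmp = rm.compare_slopes(groups)
print(f"ANCOVA slope comparison: F = {cmp.f_stat:.2f}, p = {cmp.p_overall:.4f}")

raw = [cmp.p_overall, res.p, 0.04]
adj = rm.holm_bonferroni(raw)
print(f"Holm-adjusted p-values for the family {np.round(raw, 4).tolist()}: "
      f"{np.round(adj, 4).tolist()}")
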