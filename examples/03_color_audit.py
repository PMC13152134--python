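"""Color counterfactual: can six HSV summary statistics predict the label?

A logistic model on per-image HSV statistics should be useless on a clean
dataset — color summaries carry no diagnosis. When it performs well, some
acquisition artifact (here: planted saturation spread) is confounded with
the label, and the odds ratios say which channel carries it.
"""
from otoaudit.color import color_audit
from otoaudit.synthetic import SyntheticConfig, generate_images


def provider(manifest, images):
    by = {r.image_id: im for r, im in zip(manifest.records, images)}
    return lambda record: by[record.image_id]


# Two "sites" that share the same acquisition artifact.
site_a_cfg = SyntheticConfig(n_per_class=200, saturation_bias=1.0,
                             clinical_contrast=0.0, seed=21)
site_b_cfg = SyntheticConfig(n_per_class=200, saturation_bias=1.0,
                             clinical_contrast=0.0, seed=22,
                             dataset_id="site_b")
manifest, _, images = generate_images(site_a_cfg)
ext_manifest, _, ext_images = generate_images(site_b_cfg)
by = {r.image_id: im for r, im in zip(manifest.records, images)}
by.update({r.image_id: im for r, im in zip(ext_manifest.records, ext_images)})

res = color_audit(manifest, [ext_manifest], feature_set="hsv6",
                  image_provider=lambda r: by[r.image_id])

print("AUC of the HSV-only logistic model:")
for row in res.auc_rows:
    print(f"  {row['eval_set']:>13}: {row['auc']:.3f} "
          f"(95% CI {row['ci_low']:.3f}-{row['ci_high']:.3f}, n={row['n']})")
print("  -> far above chance on color alone: the labels are predictable"
      "\n     without looking at anatomy, at both sites.")

print("\nOdds ratios (per feature standard deviation):")
for r in res.odds_ratio_rows:
    flag = "  <-- carries the artifact" if r.p_value < 0.01 else ""
    print(f"  {r.feature:>9}: OR {r.odds_ratio:6.3f} "
          f"({r.ci_low:.3f}-{r.ci_high:.3f}), p={r.p_value:.2e}{flag}")
print("  -> the saturation-spread coefficient is the significant one,"
      "\n     matching the planted bias exactly.")
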