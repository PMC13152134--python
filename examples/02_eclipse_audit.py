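"""Occlusion audit: does the classifier need the anatomy at all?

An ellipse of increasing extent blacks out the image centre; the classifier
is refit and rescored at each extent. If accuracy survives a mask that hides
the entire tympanic membrane, the model is reading something other than
pathology — framing, lighting, color — i.e. a shortcut.

Two datasets make the contrast: one whose labels are carried by a genuine
central lesion, and one where only a global color artifact separates the
classes.
"""
from otoaudit.pipeline import AuditConfig, run_experiment1
from otoaudit.synthetic import SyntheticConfig, generate_images


def provider(manifest, images):
    by = {r.image_id: im for r, im in zip(manifest.records, images)}
    return lambda record: by[record.image_id]


def sweep(name, config):
    manifest, _, images = generate_images(config)
    df = run_experiment1(
        AuditConfig(train_manifest=manifest, eclipse_extents=(0.0, 0.5, 1.0)),
        provider(manifest, images),
    )
    internal = df[df.eval_set == "internal_val"].set_index("extent")
    print(f"\n{name}")
    for extent, row in internal.iterrows():
        print(f"  extent {extent:3.1f}: AUC {row.auc:.3f} "
              f"(95% CI {row.ci_low:.3f}-{row.ci_high:.3f})")
    return internal


signal = sweep(
    "clinical signal only (lesion on the membrane, no artifacts)",
    SyntheticConfig(n_per_class=300, clinical_contrast=80.0, seed=11),
)
print("  -> AUC collapses to chance once the membrane is masked: the model"
      "\n     was using anatomy, as it should.")

artifact = sweep(
    "color artifact only (saturation spread tracks the label)",
    SyntheticConfig(n_per_class=300, saturation_bias=1.0,
                    clinical_contrast=0.0, seed=12),
)
print("  -> AUC stays high with the anatomy fully hidden: the model is"
      "\n     exploiting a shortcut that lives in the periphery.")
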