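"""Generate a digital thorax phantom and recover its lobar perfusion truth.

Builds a CT + SPECT pair with known per-lobe blood-flow shares, runs the
segmentation chain (threshold → closing → lung field → trace-based lobe
split), and compares the counted lobar fractions against the ground truth.
"""

from ppolung import (
    PhantomConfig,
    binarize_ct,
    close_mask,
    extract_lung_field,
    generate_thorax_phantom,
    lobar_fractions,
    split_lobes,
)

config = PhantomConfig(seed=7)
ct, spect, truth = generate_thorax_phantom(config)

lung_field = extract_lung_field(close_mask(binarize_ct(ct), 2))
labels = split_lobes(lung_field, truth.fissure_traces)
perf = lobar_fractions(spect.values, labels)

print("lobe   measured  truth     |error|")
for lobe, measured in perf.fractions.items():
    true = truth.lobar_perfusion_fractions[lobe]
    print(f"{lobe:5s}  {measured:.4f}    {true:.4f}    {abs(measured - true):.4f}")

# The measured column is the SPECT/CT route (masked count ratios); errors of
# a few 1e-4 come from Poisson counting noise and PSF spill across fissures.
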