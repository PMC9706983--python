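"""Per-copy sequencing coverage for a multi-copy extrachromosomal array.

A transgene array carries roughly 70-300 tandem copies; the same mapped
yield spread over more copies means shallower per-copy coverage, so the
copy-number range turns one mapped-pair count into a coverage interval.
"""

from nucprofile import estimate_array_coverage

est = estimate_array_coverage(
    mapped_pairs=100_000,
    effective_bases_per_pair=147.0,   # mean reconstructed fragment length
    probe_length=3_000,               # transgene probe reference length
    copies_low=70,
    copies_high=300,
)
print(f"formula: {est.formula}")
print(f"estimated per-copy coverage: {est.coverage_low:.1f}x (at "
      f"{est.copies_high} copies) to {est.coverage_high:.1f}x (at "
      f"{est.copies_low} copies)")
# Fewer copies concentrate the same reads on fewer templates, hence the
# upper coverage bound comes from the low end of the copy-number range.
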