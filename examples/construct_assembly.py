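"""Assemble a repelling-element construct and inspect its geometry.

Builds a construct carrying a 70 bp repelling element forward in the
upstream HindIII site and reverse in the downstream NheI site (the
"ForwardReverse" layout), then prints where everything landed on the
enhancer-centered report axis and writes the FASTA + BED annotation.
"""

from nucprofile import (
    ElementInsert,
    Orientation,
    Site,
    assemble_construct,
    placeholder_backbone,
    synthetic_element,
    to_report_coordinates,
)
from nucprofile.constructs import write_construct_fasta, write_elements_bed

backbone = placeholder_backbone()
prs = synthetic_element("PRS-322", 70)  # synthetic stand-in sequence, real length
spec = assemble_construct(
    "prs_forward_reverse",
    backbone,
    [
        ElementInsert(prs, Site.UPSTREAM_HINDIII, Orientation.FORWARD),
        ElementInsert(prs, Site.DOWNSTREAM_NHEI, Orientation.REVERSE),
    ],
)

print(f"construct: {spec.name}, {len(spec)} bp "
      f"(= {len(backbone.sequence)} bp backbone + 2 x 70 bp inserts)")
enh = spec.enhancer_interval
print(f"enhancer: [{enh.start}, {enh.end}) internally -> report offsets "
      f"[{to_report_coordinates(spec, enh.start)}, "
      f"{to_report_coordinates(spec, enh.end - 1) + 1})")
for label, ann in sorted(spec.element_intervals.items(),
                         key=lambda kv: kv[1].interval.start):
    iv = ann.interval
    print(f"{label}: [{iv.start}, {iv.end}) {ann.orientation.value}, report "
          f"offsets [{to_report_coordinates(spec, iv.start)}, "
          f"{to_report_coordinates(spec, iv.end - 1) + 1})")

write_construct_fasta(spec, "prs_construct.fasta")
write_elements_bed(spec, "prs_construct.bed")
print("wrote prs_construct.fasta / prs_construct.bed")
# Negative offsets are bp upstream of the enhancer center, positive are
# downstream; the enhancer itself always spans [-45, +45).
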