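"""Map proteins to the charge-hydropathy plane and classify them.

A protein's two coordinates — mean normalized hydropathy H and absolute
normalized net charge R — are compared against the published boundary
line for each bundled scale: points above the line (charge-rich,
hydropathy-poor) are predicted intrinsically disordered.
"""

from idphydro import (
    SequenceRecord,
    builtin_boundary,
    ch_point,
    classify,
    decision_score,
    get_builtin_scale,
)

proteins = [
    SequenceRecord("hydrophobic_core", "ILVFILVFMWYC" * 8),
    SequenceRecord("charged_flexible", "KKEKSPKKEGSE" * 8),
    SequenceRecord("mixed", "ACDEFGHIKLMNPQRSTVWY" * 5),
]

for scale_name in ("idp_hydropathy", "guy", "kyte_doolittle"):
    scale = get_builtin_scale(scale_name)
    boundary = builtin_boundary(scale_name)
    print(f"\n{scale_name}  (boundary: R = {boundary.a} * H + {boundary.b})")
    for rec in proteins:
        pt = ch_point(rec, scale)
        label = classify(pt, boundary)
        score = decision_score(pt, boundary)
        print(f"  {rec.id:18s} H={pt.H:.3f} R={pt.R:.3f} "
              f"score={score:+.3f} -> {label}")

print("\nH is the composition-weighted mean of the 0-1 normalized scale; "
      "R is |(#R + #K - #E - #D)| / length.  A positive score means the "
      "point lies above the boundary line, i.e. predicted disordered.")
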