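"""Marker-vs-control focus perturbation at the six study positions.

An occluding screen (the acoustic stand-in for a biopsy marker) is placed
in-plane with the natural focus and 7 mm beyond it, centered and offset 3 mm
along each transverse axis.  For each position the marker and control scans
are projected into a volume and compared.
"""

import fusmark as fm

cfg = fm.AcousticExperimentConfig(
    n=31,                      # 1.5 x 1.5 cm scan window at 0.5 mm
    z_range_mm=(-10.0, 10.0),
    z_step_mm=1.0,
    source_points=20000,
)
table = fm.run_acoustic_experiment(cfg, seed=0)

cols = ["marker_plane_mm", "offset_x_mm", "offset_y_mm",
        "peak_change_fraction", "focus_volume_change_fraction",
        "displacement_total_mm", "insertion_loss_db"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:8.3f}"))

print("\nNegative peak_change means the marker sheds focal pressure "
      "(strongest with the marker at the natural focus); a 3 mm lateral "
      "offset leaves the focus nearly untouched, mirroring the finding that "
      "targets outside the beam's half-maximum are treatable.")
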