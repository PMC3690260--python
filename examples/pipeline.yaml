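# Full-pipeline configuration: the reference synthetic study.
# Every value shown is the default; override as needed.
phantom:
  amplitude_mm: 23.0      # peak-to-peak SI breathing excursion
  period_s: 4.0           # one full cycle over the scan
geometry:
  n_views: 200
  increment: 1.0          # deg/view (199 deg short scan)
  sod: 800.0              # mm
  sdd: 1200.0             # mm
  nu: 640
  nv: 480
  spacing: 0.616          # mm/px
  scan_time: 4.0          # s
tracking:
  seed_point: auto        # or [u, v] pixel coordinates of the apex in frame 0
triangulation:
  offset_deg: 90.0
  mode: rectified_corrected
signal:
  ref_index: 0
  sigma: 2.0              # frames
reconstruction:
  grid: 128
  spacing: 2.0            # mm
seed: 0
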