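# Example configuration for `aneupore run --config docs/example_run.yaml`:
# a simulated five-sample multiplexed run at the assay's design depth.
mode: simulate
seed: 42
out_dir: runs/panel
n_reads: 10000
per_base_error: 0.10
n_barcodes: 5
n_ua: 9000
min_overlap: 20
max_error_rate: 0.20
min_length: 50
min_score_fraction: 0.5
margin: 1
sd_normal: 0.0897
z_threshold: 3.5
reference: expected
samples:
  - {sample_id: S01, barcode_id: BC01, karyotype: "45,XO"}
  - {sample_id: S02, barcode_id: BC02, karyotype: "47,XY,+21"}
  - {sample_id: S03, barcode_id: BC03, karyotype: "46,XX"}
  - {sample_id: S04, barcode_id: BC04, karyotype: "46,XY"}
  - {sample_id: S05, barcode_id: BC05, karyotype: "47,XY,+18"}
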