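"""Run the whole pipeline end to end from a config.

Equivalent to `bcellomics run --config examples/demo_config.json --out DIR`;
writes every stage's files plus a checksum manifest, deterministic for a
fixed seed.
"""

import json
import sys
from pathlib import Path

from bcellomics import RunConfig, run_all
from bcellomics.io import read_json

config_path = Path(__file__).parent / "demo_config.json"
out_dir = Path(sys.argv[1]) if len(sys.argv) > 1 else Path("demo_out")

cfg = RunConfig.from_dict(read_json(config_path))
manifest = run_all(cfg, out_dir)

s = manifest["summary"]
print(f"wrote {len(manifest['files'])} files to {out_dir}")
print(f"DML: {s['dml']['n_dml']} of {s['dml']['n_tested']} CpGs "
      f"({s['dml']['n_hypo']} hypo / {s['dml']['n_hyper']} hyper)")
print(f"DEG: {s['deg']['n_deg']} ({s['deg']['n_up']} up / {s['deg']['n_down']} down)")
print(f"DAR: {s['dar']['n_dar']} ({s['dar']['n_more_accessible']} more accessible)")
print(f"QC: {s['atac_qc']['n_pass']} ATAC samples pass; "
      f"failed: {s['atac_qc']['failed_samples'] or 'none'}")
print(f"top DML-proximal motif: {s.get('motif_enrichment_top')}")
if "spearman_dme_dexpr" in s:
    print(f"Spearman rho (methylation vs expression change): "
          f"{s['spearman_dme_dexpr']['rho']:.2f}")
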