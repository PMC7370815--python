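#!/usr/bin/env python
"""Run the full contrast analysis on a user-supplied image collection.

This script is NOT part of the test suite: it exists for users who have
their own high-resolution plates (e.g. downloaded manually from a museum's
online collection) and want the chronological contrast timeline and the
two-condition comparison for them.

Expected layout: a directory of images plus a catalog CSV with columns
``image_id, order_index, date_label, condition, path`` (condition is
``low`` or ``high``; paths may be relative to the catalog's directory).
The packaged 28-row catalog (``contraspect.fixture_catalog_path()``) shows
the expected condition layout for a 28-item, 19-low/9-high cohort: rename
its ``path`` column entries to point at your files.

The comparison p-value is printed for inspection, not asserted against any
reference: it depends on the exact plates, their resolution and any
cropping, none of which are standardised.

Usage:
    python scripts/analyze_plates.py --catalog plates/catalog.csv --out results/plates
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from contraspect import PipelineConfig
from contraspect.cli import run_compare, run_contrast


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--catalog", required=True)
    parser.add_argument("--out", required=True)
    parser.add_argument("--metric", default="rms", choices=["variance", "rms"])
    parser.add_argument(
        "--sidedness", default="two_sided", choices=["two_sided", "one_sided_greater"]
    )
    parser.add_argument("--crop-fraction", type=float, default=0.0)
    parser.add_argument("--max-dim", type=int, default=None)
    args = parser.parse_args()

    config = PipelineConfig(
        catalog_path=args.catalog,
        output_dir=args.out,
        metric=args.metric,
        sidedness=args.sidedness,
        crop_fraction=args.crop_fraction,
        max_dim=args.max_dim,
    )
    contrast_csv = run_contrast(config)
    json_path, plot_path = run_compare(config, contrast_csv)
    payload = json.loads(Path(json_path).read_text())
    print(f"per-image contrasts: {contrast_csv}")
    print(f"timeline plot:       {plot_path}")
    print(
        f"comparison: U={payload['u_statistic']} p={payload['p_value']:.4g} "
        f"({payload['method']}, {payload['sidedness']})"
    )


if __name__ == "__main__":
    main()
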