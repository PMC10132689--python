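#!/usr/bin/env python
"""Grooming networks and node metrics from the reference scan table.

Re-tallies the scan table written by 01_build_reference_dataset.py into
directed weighted networks (index-of-interactions standardization),
computes the five node metrics plus their group-size-standardized variants,
and runs the inter-metric Pearson screen (|r| > 0.70 flags redundancy).
Outputs land in results/metrics/.
"""

import argparse
from pathlib import Path

from groomnet.data_model import read_scan_table, write_adjacency
from groomnet.network_build import build_networks
from groomnet.network_metrics import (compute_metrics_table,
                                      metric_correlation_screen,
                                      standardize_metrics)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--scan-table", type=Path,
                        default=Path("results/reference/scan_table.csv"))
    parser.add_argument("--out", type=Path, default=Path("results/metrics"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    obs = read_scan_table(args.scan_table)
    networks = build_networks(obs)
    net_dir = args.out / "networks"
    net_dir.mkdir(exist_ok=True)
    for net in networks:
        write_adjacency(net.nodes, net.W, net_dir / f"{net.group_id}.csv")

    table = standardize_metrics(compute_metrics_table(networks, obs))
    table.to_csv(args.out / "node_metrics.csv", index=False)
    screen = metric_correlation_screen(table)
    screen.to_csv(args.out / "correlation_screen.csv", index=False)

    males = table[table.sex == "male"]
    print(f"{len(networks)} networks; {len(table)} metric rows")
    print(f"mean male out-strength: {males.out_strength.mean():.3f}")
    strongest = screen.loc[screen.r.abs().idxmax()]
    print(f"strongest metric correlation: r({strongest.metric_a}, "
          f"{strongest.metric_b}) = {strongest.r:.2f}"
          + ("  [flagged > 0.70]" if strongest.flagged else ""))


if __name__ == "__main__":
    main()
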