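#!/usr/bin/env python
"""Stub: convert externally published logic-table layouts to `.bnet`.

Large curated signaling models are typically distributed as per-node truth
tables or interaction lists in spreadsheet/CSV form, with one publisher-
specific layout per source.  This script is the intended adapter from such
a layout to the `.bnet` dialect consumed by boolscape (one
``TARGET, EXPRESSION`` line per regulated node, see
``boolscape.network``); it is a stub until a concrete source layout is in
hand, because column conventions cannot be guessed reliably.

To implement an adapter:
  1. read the source table (pandas handles CSV/TSV/XLSX),
  2. for each regulated node, build either a Boolean expression or a truth
     table over its regulators,
  3. emit expressions via ``boolscape.network.serialize_bnet`` (a truth
     table over parents p1..pk can always be emitted as a disjunction of
     its ON rows: ``(p1 & !p2 & ...) | ...``),
  4. validate with ``boolscape validate model.bnet`` — node and link counts
     should match the source publication.
"""

import argparse
import sys


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("source", help="publisher-specific logic-table file")
    parser.add_argument("--out", help="output .bnet path")
    parser.parse_args()
    print("not implemented: adapt this stub to the source table layout "
          "(see module docstring)", file=sys.stderr)
    return 2


if __name__ == "__main__":
    raise SystemExit(main())
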