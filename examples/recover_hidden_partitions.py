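"""Recover edge partitions of drugs whose molecular graphs were never
published, from their tabulated index values alone.

The four integer-valued indices (M1, M2, HM, F) are matched exactly by a
branch-and-bound search over degree-pair counts; the remaining seven indices
select among candidates.  A tiny residual means the published row is fully
explained by an integer partition; an infeasible row means the row is
internally inconsistent as printed (the table has typos, which the fixture
keeps verbatim and the validator flags).
"""
from tiqspr import fixtures
from tiqspr.molgraph import InfeasiblePartitionError, recover_partition

table = fixtures.load_index_table()
violations = fixtures.validate_index_table(table)
print("rows violating HM = F + 2*M2 as printed:",
      {drug: int(dev) for drug, dev in violations.items()})
for drug in ["Diclofenac", "Estradiol", "Ketorolac"]:
    try:
        rec = recover_partition(table.loc[drug].to_dict())
        part = {f"({a},{b})": n for (a, b), n in rec.partition.items()}
        print(f"{drug}: {part}  residual={rec.residual:.2e}  unique={rec.unique}")
    except InfeasiblePartitionError as exc:
        print(f"{drug}: infeasible as printed -- {exc}")
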