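"""Bin a small genome, read a contact list, and build the multigraph.

Shows the two edge classes: one elastic genomic edge per 10 kb bin, plus
hard contact springs (quarter rest length) from Hi-C records.
"""

import io
import tempfile
from pathlib import Path

import hicspring as hs

# two toy chromosomes
bins = hs.make_bins({"chr1": 55_000, "chr2": 30_000}, bin_size=10_000)
print(f"{bins.n_chrom} chromosomes -> {bins.n_bins} bins")
print(bins.bin_table)

# a tiny contact list: chrom1 pos1 chrom2 pos2 count
contacts_txt = """\
chr1\t5000\tchr1\t45000\t4
chr1\t5000\tchr2\t15000\t2
chr2\t15000\tchr1\t3000\t1
chr1\t21000\tchr1\t22000\t9
"""
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "contacts.tsv"
    path.write_text(contacts_txt)
    table = hs.read_contacts(path, bins)

print("\ncanonical records (duplicates merged, self-loops dropped):")
print(table.records)

mg = hs.build_multigraph(bins, table)
print(f"\nmultigraph: {mg.n_nodes} nodes "
      f"({bins.n_bins} bin starts + {bins.n_chrom} chromosome ends), "
      f"{mg.n_genomic_edges} genomic edges, {mg.n_contact_edges} contact edges")
print(f"genomic rest lengths (short last bins are shorter): {mg.genomic_rest}")
print(f"contact rest length = L1/4 = {mg.contact_rest[0]}, "
      f"stiffness k2/k1 = {mg.k2 / mg.k1:g}")
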