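import numpy as np
import pytest

from geotypekit import (
    AlleleDatabase,
    AllelicProfile,
    STRegistry,
    find_amplicon,
    trim_in_frame,
    type_genome,
    type_matrix,
)
from geotypekit.errors import (
    AmbiguousAmpliconError,
    IncompleteProfileError,
    LocusNotFoundError,
    TruncatedAmpliconError,
    UncallableAlleleError,
)
from geotypekit.io_formats import LOCUS_ORDER
from geotypekit.linkage_stats import HaplotypeMatrix
from geotypekit.mlst_typing import TrimSpec, default_trim_spec, revcomp
from geotypekit.synthetic_data import SimulationConfig, simulate_genomes


@pytest.fixture(scope="module")
def ala1():
    from geotypekit import load_table3_fixture

    return next(p for p in load_table3_fixture() if p.locus == "ALA1")


def planted_scaffold(primer, rng, insert_len=None, pad=100):
    insert_len = insert_len or primer.locus_size - len(primer.forward) - len(primer.reverse)
    insert = "".join(rng.choice(list("ACGT"), size=insert_len))
    amplicon = primer.forward + insert + revcomp(primer.reverse)
    left = "".join(rng.choice(list("ACGT"), size=pad))
    right = "".join(rng.choice(list("ACGT"), size=pad))
    return left + amplicon + right, amplicon, pad


class TestFindAmplicon:
    def test_planted_amplicon_recovered_at_planted_coordinates(self, ala1, rng):
        scaffold, amplicon, start = planted_scaffold(ala1, rng)
        amp = find_amplicon([("scaf1", scaffold)], ala1)
        assert amp.sequence == amplicon
        assert len(amp.sequence) == ala1.locus_size
        assert (amp.scaffold_id, amp.start, amp.end, amp.strand) == (
            "scaf1", start, start + ala1.locus_size, "+",
        )

    def test_reverse_complemented_scaffold_flips_strand_only(self, ala1, rng):
        scaffold, amplicon, _ = planted_scaffold(ala1, rng)
        amp = find_amplicon([("scaf1", revcomp(scaffold))], ala1)
        assert amp.sequence == amplicon
        assert amp.strand == "-"

    def test_genome_without_primers_not_found(self, ala1, rng):
        junk = "".join(rng.choice(list("ACGT"), size=2000))
        with pytest.raises(LocusNotFoundError):
            find_amplicon([("scaf1", junk)], ala1)

    def test_two_plantings_are_ambiguous(self, ala1, rng):
        s1, _, _ = planted_scaffold(ala1, rng)
        s2, _, _ = planted_scaffold(ala1, rng)
        with pytest.raises(AmbiguousAmpliconError):
            find_amplicon([("scaf1", s1 + s2)], ala1)

    def test_tolerates_internal_primer_mismatches(self, ala1, rng):
        scaffold, amplicon, start = planted_scaffold(ala1, rng)
        # mutate base 3 of the forward primer annealing site (internal, 5' side)
        pos = start + 3
        mutated = scaffold[:pos] + ("A" if scaffold[pos] != "A" else "C") + scaffold[pos + 1 :]
        amp = find_amplicon([("scaf1", mutated)], ala1)
        assert amp.start == start

    def test_mismatch_in_three_prime_terminus_blocks_annealing(self, ala1, rng):
        scaffold, amplicon, start = planted_scaffold(ala1, rng)
        pos = start + len(ala1.forward) - 1  # 3'-terminal base of fwd primer
        mutated = scaffold[:pos] + ("A" if scaffold[pos] != "A" else "C") + scaffold[pos + 1 :]
        with pytest.raises(LocusNotFoundError):
            find_amplicon([("scaf1", mutated)], ala1)

    def test_size_window_rejects_wrong_product(self, ala1, rng):
        scaffold, _, _ = planted_scaffold(ala1, rng, insert_len=1000)
        with pytest.raises(LocusNotFoundError):
            find_amplicon([("scaf1", scaffold)], ala1)


class TestTrimInFrame:
    def test_offset_slicing(self):
        assert trim_in_frame("AAGGGTTTCC", TrimSpec(2, 6)) == "GGGTTT"

    def test_default_spec_is_leading_codon_multiple(self):
        spec = default_trim_spec(424)
        assert (spec.offset, spec.length) == (0, 423)
        assert trim_in_frame("A" * 424, spec) == "A" * 423

    def test_too_short_amplicon_rejected(self):
        with pytest.raises(TruncatedAmpliconError):
            trim_in_frame("AAGGG", TrimSpec(0, 6))


class TestAlleleDatabase:
    def test_first_discovery_is_allele_one(self):
        db = AlleleDatabase("PGM2")
        assert db.assign_allele("ACGTTT") == 1

    def test_resubmission_is_idempotent(self):
        db = AlleleDatabase("PGM2")
        db.assign_allele("ACGTTT")
        assert db.assign_allele("ACGTTT") == 1
        assert len(db) == 1

    def test_discovery_order_numbering(self, rng):
        # eight distinct variants fed in a fixed order get numbers 1..8
        base = "".join(rng.choice(list("ACGT"), size=60))
        variants = [base] + [
            base[:i] + ("A" if base[i] != "A" else "C") + base[i + 1 :] for i in range(7)
        ]
        db = AlleleDatabase("PGM2")
        assert [db.assign_allele(v) for v in variants] == list(range(1, 9))

    def test_ambiguous_bases_uncallable(self):
        db = AlleleDatabase("ALA1")
        with pytest.raises(UncallableAlleleError):
            db.assign_allele("ACGTN")

    def test_length_mismatch_requires_alignment(self):
        from geotypekit.errors import AlignmentRequiredError

        db = AlleleDatabase("ALA1")
        db.assign_allele("ACGTTT")
        with pytest.raises(AlignmentRequiredError):
            db.assign_allele("ACGT")

    def test_fasta_round_trip(self):
        db = AlleleDatabase("GLN4")
        for seq in ("ACGTTT", "ACGTTA", "AAGTTA"):
            db.assign_allele(seq)
        db2 = AlleleDatabase.from_fasta_records("GLN4", db.to_fasta_records())
        assert db2.alleles == db.alleles


class TestSTAssignment:
    def test_first_profile_is_st_one(self):
        reg = STRegistry()
        assert reg.assign_st(AllelicProfile("x", (1, 1, 1, 1, 1, 1))) == 1

    def test_incomplete_profile_rejected(self):
        reg = STRegistry()
        with pytest.raises(IncompleteProfileError):
            reg.assign_st(AllelicProfile("x", (1, 1, -1, 1, 1, 1)))

    def test_table_row_order_reproduces_published_sts(self, table1):
        matrix, strains = table1
        sts, registry = type_matrix(matrix)
        assert sts == [s.st for s in strains]
        assert len(registry) == 15
        by_id = dict(zip(matrix.strain_ids, sts))
        assert by_id["15"] == 1
        assert by_id["21"] == 3

    def test_permuting_strains_preserves_partition_structure(self, table1, rng):
        matrix, _ = table1
        order = rng.permutation(matrix.n)
        shuffled = HaplotypeMatrix(
            tuple(matrix.strain_ids[i] for i in order),
            matrix.loci,
            matrix.alleles[order],
        )
        sts_a, _ = type_matrix(matrix)
        sts_b, _ = type_matrix(shuffled)
        by_id_b = dict(zip(shuffled.strain_ids, sts_b))
        groups_a, groups_b = {}, {}
        for sid, st in zip(matrix.strain_ids, sts_a):
            groups_a.setdefault(st, set()).add(sid)
        for sid in matrix.strain_ids:
            groups_b.setdefault(by_id_b[sid], set()).add(sid)
        assert sorted(groups_a.values(), key=sorted) == sorted(
            groups_b.values(), key=sorted
        )


class TestEndToEndTyping:
    def test_planted_loci_recovered_for_all_strains(self, primers):
        cfg = SimulationConfig(
            seed=17, n_strains=20, n_scaffolds=5, scaffold_length=5000,
            alleles_per_locus=4,
        )
        genomes, _, truth = simulate_genomes(cfg)
        truth_by = {(r["strain"], r["locus"]): r for r in truth}
        mlst_primers = [p for p in primers if p.mlst2019]
        dbs = {locus: AlleleDatabase(locus) for locus in LOCUS_ORDER}
        registry = STRegistry()
        recovered = planted = 0
        call_partition, truth_partition = {}, {}
        for sid, records in genomes.items():
            profile, st, amplicons = type_genome(
                records, mlst_primers, dbs, registry, strain_id=sid
            )
            for j, locus in enumerate(LOCUS_ORDER):
                t = truth_by[(sid, locus)]
                planted += 1
                recovered += (
                    amplicons[locus].sequence == t["amplicon"]
                    and amplicons[locus].start == t["start"]
                    and amplicons[locus].strand == t["strand"]
                )
                call_partition.setdefault((locus, profile.alleles[j]), set()).add(sid)
                truth_partition.setdefault((locus, t["allele_idx"]), set()).add(sid)
        assert recovered == planted == 20 * 6
        # called allele partition equals the planted one (numbering aside)
        assert sorted(call_partition.values(), key=sorted) == sorted(
            truth_partition.values(), key=sorted
        )
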