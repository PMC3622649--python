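"""Independent oracles used by the test suite (kept separate from the
implementation paths they check)."""

from metagun.dna import START_CODONS, STOP_CODONS, revcomp


def brute_force_orfs(seq: str, min_len: int = 60):
    """Independent six-frame scanner: maximal stop-free codon runs."""
    found = set()
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            codons = [
                (p, s[p : p + 3]) for p in range(frame, len(s) - 2, 3)
            ]
            run: list[tuple[int, str]] = []
            prev_stop = False

            def flush(run, has_stop, touched_left):
                if not run:
                    return
                starts = [p for p, c in run if c in START_CODONS]
                if touched_left:
                    start, complete5 = frame, False
                elif starts:
                    start, complete5 = starts[0], True
                else:
                    return
                end = run[-1][0] + 3 + (3 if has_stop else 0)
                if end - start >= min_len:
                    found.add((strand, frame, start, end, complete5, has_stop))

            touched_left = True
            for p, c in codons:
                if c in STOP_CODONS:
                    flush(run, True, touched_left)
                    run, touched_left = [], False
                else:
                    run.append((p, c))
            flush(run, False, touched_left)
    return found


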