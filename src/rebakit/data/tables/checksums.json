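{
 "table_a.csv": "f55092a6443c78c63516aa7ee0c0a6df317b086e210ce6ef7acb56b0546d04b3",
 "table_b.csv": "5bedc3cf965666bb836f818a0011fd60d3fcd78be05127138504a631ea9adbbd",
 "table_c.csv": "cdc744567dfa73bf38c77e38f7d8fe6ad73d98605309685450e5ddbd673462e4"
}
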