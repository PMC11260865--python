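{
 "bp_targets.txt": "7f41c6dbcef0c81538811c709daf8db751f75d92f85d6b66364e10851a6c0cfd",
 "conjugate_whitelist.txt": "27a3a77c2866e7ef10345289d13c759cc8cd3f5ecaa4fdebdaa1376d2326d631",
 "guidelines.tsv": "8baa33f01bf2f01df8d7d22e912bf71426675e4df9f9f3ce0c8428c85c581c10",
 "manual_symbol_map.tsv": "166c5ee3416d6d17f2e545b69477f189cc02bc34ac501c197c81e02fffc54a0c",
 "non_druggable_targets.txt": "906e4d759957bfd76c4ecc99f7406715d630332a86470bb49380d7de59d0171b",
 "salt_lexicon.txt": "a34c05da2bba0a3e6201cb4f83e78d3c52521f427ef9f9ab521996c3e7604eee",
 "table1.tsv": "3e46f85e9316023759f65fa6489f6586ade610d3c86c67ff4112c8451b088ff8",
 "table2.tsv": "639ad5f492a157e9e90a298b3e76b1c22bb40ad441fdba617fe8c6bd5ac01042"
}
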