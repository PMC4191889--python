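; curated synthetic reference set: histone sequences constrained to the
; published C. elegans residue numbering and cross-species site map
>his-2a family=H2A species=celegans canonical histone H2A
MSGRGKGGKAKTGAKAKSRSSRAGLQFPVGRVHRLLRKGNYAERVGAGAPVYLAAVLEYL
TAEILELAGNAARDNKKTRIIPRHLQLAVRNDEELNKLLGRVTIAQGGVLPNIQAVLLPK
KTESHHKAKGK
>his-2b family=H2B species=celegans canonical histone H2B
MSAPAPKKGSKKATKAQSAAKKDGKKRKRSRKESYSVYVYKVLKQVHPDTGISSKAMGIM
NSFVNDIFERIAGEASRLAHYNKRSTITSREIQTAVRLLLPGELAKHAVSEGTKAVTKYT
SSK
>his-3 family=H3 species=celegans canonical histone H3
MARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHRYRPGTVALREIRRYQKSTE
LLIRKLPFQRLVREIAQDFKTDLRFQSSAVMALQEASEAYLVGLFEDTNLCAIHAKRVTI
MPKDIQLARRIRGERA
>his-4 family=H4 species=celegans canonical histone H4
MSGRGKGGKGLGKGGAKRHRKVLRDNIQGITKPAIRRLARRGGVKRISGLIYEETRGVLK
VFLENVIRDAVTYTEHAKRKTVTAMDVVYALKRQGRTLYGFGG
>htas-1 family=variant species=celegans sperm-specific histone H2A variant
MTSRGKTGGKAKSRSELSRSAKAGLQFPVGRIHRLLRKGNYAQRVGTGAPVYLAAVLEYL
AAEVLELAGNAARDNKKSRIIPRHLQLAIRNDEELNKLFSGVTIAQGGVLPNIHSVLLPK
KKAKEDDKENNS
>htz-1 family=variant species=celegans histone H2A.Z ortholog
MAGGKAGKDSGKAKSKAVSRSQRAGLQFPVGRIHRHLKSRTTSHGRVGATAAVYSAAILE
YLTAEVLELAGNASKDLKVKRITPRHLQLAIRGDEELDSLIKATIAGGGVIPHIHKSLIG
KKGQQKTA
>his-1 family=H1 species=celegans linker histone H1
MSDSAVATSAPAKAKAVKAKASKELSVSELILKAVSASKERSGVSLAALKKSLAAGGYDV
EKNNSRVKIAVKSLVTKGTLVQTKGTGASGSFKLSKKAASPKKAAKKAPKKAKKPAAAAK
KPKKVAAKKK
>his-3.3 family=variant species=celegans replication-independent histone H3 variant
MARTKQTARKSTGGKAPRKQLATKAARKSAPSTGGVKKPHRYRPGTVALREIRRYQKSTE
LLIRKLPFQRLVREIAQDFKTDLRFQSSSIGALQEASEAYLVGLFEDTNLCAIHAKRVTI
MPKDIQLARRIRGERA
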