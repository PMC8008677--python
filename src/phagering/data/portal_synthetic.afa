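>portal_synthetic_00 category=portal synthetic
YVDMMGMHNKVIAQNCLQYWNKTIEPEHHTNFSVHKGQEGKHNCLNVKNMFQLAPAGKKWHEMLSIVKHQWQQGAWYDEYQAESNCEYSETKSTGQDTDMTTHCYEGCIGWDQYAMNEFRRHWNFPWPQW
>portal_synthetic_01 category=portal synthetic
YGDIRGMHNKNIMQNCLQYWNKTIRPEHHTNHNYHKWKAGKHNCLNVKKTFQNAPAGKKWRYMLSIVAHQWQQGAWYDEYQAESNCEYSEPKSTGQDYDMTSHCYEGCIGDDQYAMNEGRRHWEFPFPNW
>portal_synthetic_02 category=portal synthetic
YVDIRGMHNKVIANNCLQYWNKTIEPEHHTNHNYHKFKPGKHNCLNVKKTFQLAWAGKKLHYMLSIVKHQWQQGCSYDENQAESNCEYSETCSTGQDYDMTTHCYEGCIGDAQYAKKEFRRHWEIPCPQW
>portal_synthetic_03 category=portal synthetic
YVDIRGMHNLVIAQNMLQYWNKTIEPELYTNHNYHKGKQGKHNCLNMKKTFQLAPAGKKWHYMVSIVQRQWQQGAWYDEYQKESNCEYNETFSTGQDYDMTTHCYEGCIGDDQYIMNEFRRQWEPPFPQW
>portal_synthetic_04 category=portal synthetic
YVDIRPMHNKIGAQNCLQYWNKWIEPEHHTNHNYHKGAAGKHNCLNVKKTKQLAPAGKKWHYMLMIVEEQWQQGAWYDEYQAYHNCEYNETKSTGQDYDMTFWCYEGCIGDDQYAMNAFRRHWEFKFPQW
>portal_synthetic_05 category=portal synthetic
YVDIRGLCNKVIQQNCLQYWNKTINPEHHTNHNYKKEKAGKHNRLNVKKTFGLAPAGEKWPYMLSIVKHQWQQGAWYSEYQAWSNCEYNETKSTVQDYVMTTHCYEGCIRDDQYAMNEFRRHWEFPFPQW
>portal_synthetic_06 category=portal synthetic
YVKIRGMHNKHIAQNHLQYWNKTIEPEHHTNSNYHKGKAGKHNCLNVKKTFQLAPAGKTWHYMLSIVKHQWQQGAWNREYQAESNDESSETKSTGQDPDMTTHCAEGCIGDDQYAFNEFRNHNEFPFPQW
>portal_synthetic_07 category=portal synthetic
DVDIRGMHNKVIAQNCLQYWTKTIEPIHHTNHNYHKGKAGKHNCLNVKKTFQLRPAGKKWHYMLSIVKHQKQQGAWYDEYMAPDNCEYSETKSTGQDYVMTEHCYEECIGDDQYAMNEPRRYWEFIFPQW
>portal_synthetic_08 category=portal synthetic
YVDIRGMHNVVIAQACLQYWNKTIEPEHHTNHNYHKKKAGKHNCLNVKKTFQLAPAGDKWHYMLSIVKHQWQQGAWYDEYQIESNCEYSETKSTGQDYDMTTHNYEGCIGDDHYRMNEFRRHWEFPFGQW
>portal_synthetic_09 category=portal synthetic
YVDIRGMHNKVIAQNIDQYWNKTIEPEHHTNHNYHKGKAGKHVCLNVKKTFQLAPAGKHWHYMLSTVKHQWQQNAWSDEYQAYLNCEYCEYKSTGPDYDMTTHCYEGCIGTDQYAMNESRRLWEFPFPQW
>portal_synthetic_10 category=portal synthetic
YVDIRGVHMKVIAQKCLQYWNKTIEPEHHTNHNYWKGKWGMHNWLCVKPTFQLAPAAKKWHHMLSIVKHQWQQGAWTDEYWAESNNEYSETKSTGQDYDMTTHFCEGCIGDDQYAMNEARRHWEFPFPQA
>portal_synthetic_11 category=portal synthetic
NVDIRGMNNKVIAQDCLQYWEKTIEPAHHTNHYYHKGKAGKHNCLNVKKPFQLAPAGDKWHKMASIVKHQWQQGAWKDEYQAELNCESSETKGTGQDYDLTTHVHEGIAGDDQYAMNELRRHWEFPFPQW
>portal_synthetic_12 category=portal synthetic
YVDIRGMHNKVIAQNNLQYWNKTIEFEHHTNHNYHKGKAGKHNCLNVKQTFQLAPAGKKWHYMLAIVKMQWQQGQWYAEYQAENNCYYSETFGTGQDYDMTTHCYEGCIGDDQAAMNPFRRHWEFPFPQW
>portal_synthetic_13 category=portal synthetic
YVDIRKMHNKVIAQNCFQYWNKTIEPEHHTNHNYVEGKMGKHNPLNVKKTFQLAPAVKKQHYMLGIVKHQWEQGAWYDEYKAECPCDYSETKHTGQSYDMTTHCYWGCFGDDQGAMNEFRRHWDFPFPQW
>portal_synthetic_14 category=portal synthetic
YVDERGMHNAEIAQNCLQYTNKTIEQERHTNHNTHKGKAVHHNCLYVKKTFQLAQAGKKWHYMHWIVKHQWQQGAWYDEYSASSNCETSETSSTGQDYDNTTHCYEGCIGDDQYRMNEHRRHWEFPFPQW
>portal_synthetic_15 category=portal synthetic
YVDIQGMHNKVIAQACLQYWNKTIEPRMHTAHNFHWGKAGKHNCLNVKKTFQHAPMGKKWHYMLSIVKHQWQCGAWYLEYQAESNCEYSETKSTGQDYDMTTHEYEGCIGDDQIAMNEFRRHWEDKFPQW
>portal_synthetic_16 category=portal synthetic
YCDICGPHNKVIAQNCLQYWNKTIESEHHTNHNYHKGKEGKPQCLNVKITFQLAPAGKKWHYMLSLVKHQWQQGAWYDEYQAESNCEYWETKSTGQDYDMTTHCYEGCIGDDQYAMNMFRRAWEFPFPQW
>portal_synthetic_17 category=portal synthetic
YVDIRGMQNKVSAQNCLQYWNVHHEPEHHTCHNYHKGKEEKHNCLNVKKTAQLACAGKKWHYMLAIVKHQWQQTTWYDEYQTESNCEYSETKSTGQDYDMTTHLYEGCIGDDQYAMNEFSVHWEFPFPQW
>portal_synthetic_18 category=portal synthetic
YVDIRVMHNKVIAQNCLQLWNKTIEPETHHNHNDWKFKAGKHNSLNVAKTFNLAPAGHKWLYMLFFHKHQWQQGAMIDEYQAERNCEASETKSTGQLYDMTTHCHEGCIGDDQYAMNEFWRHWEFPFPQW
>portal_synthetic_19 category=portal synthetic
YVDIRGSHNKVIAQNLLQYWNKTIGPFHHRNHNYLKGKAHKHCCLNVKKTFQLAPAGKKKHYMLSIVKHQWQQGAWYFEYQAESVEEYSETKSTGQDYDMTTHCYEGCIGDDQYAMNEFRRHCGFPFPQW
>portal_synthetic_20 category=portal synthetic
YLDINVMENKVTAQNCLQYWNKTIEPEHHTNHNYHKGKAGKHNCLWVKKTFQLIPAGKKWHYMLSIVKHQWQQGAWYDEYQAESNCEYSETKSYGQDYDMTTWCYEGCQGDDQYAMNEFRRHWEFPFPQW
>portal_synthetic_21 category=portal synthetic
YVDIMGMMNKVIAQNCLQYWLKTIEPEHHTNHNYHKGKAGKHNQLNVFKTFQLAPAGKKWHYMLSIVKHQWQSGVWYDEYQAESVCEYSETKSTGQDYDMTTHCYEGCIEDDQYAMNEFQRHWEFPFPQW
>portal_synthetic_22 category=portal synthetic
YVDIRGMHNMVIAQNRNQYWNKTQEPEHGTNHAYHKGKKGKHNCLNVKKTFQLAPAGKKWHYMLSIVKHQWQQGAIYDRYQAESNCEYSETKSMGQDYDMTTHCYEGCIGDDFYAMNEFRRHREFPFPQW
>portal_synthetic_23 category=portal synthetic
YYDIREMHRKEIAQNCLQYWNKTIYPEHHTNHNYHKGKAGKHNCLNVKKTFLLAPAGKKWHYMLSIVKHVWQQGAWYDEYQAYSNCYYSETKSTGQDYDMTTHCYQGCIGDDQYAMNEFRRHWEFPFPQW
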