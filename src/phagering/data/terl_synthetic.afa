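>terl_synthetic_00 category=TerL synthetic
TANDLSPAKRQLDKTYPAKNFATAWAPHYCSQFLHYITNRSCSKGNHPTPQADEKWYSWMKDHTSDECRKIMCQHIEVLRPCISVRVQWRWQNRGFFYPYDIWHTRQHVFHSHKWGYEPSKIGLWIVNIGFYEGHDDIKP
>terl_synthetic_01 category=TerL synthetic
TNNQRSMKKRQLDGTYPAKRFATAWAPLYLVQFLHRITNRSCSKGNHFTPQADCGWYSWMKQHISDECHKISCQHIEVLRPCISVRVQWRWYNRGFFYPVDIWHHRQHVFHSHKWGYEPSKIDLWIVWIMFYEGHDIIKP
>terl_synthetic_02 category=TerL synthetic
TANDMSMKKRQLDRTYPAKLFATARAPHYRVSFVHRITNRSCSKGNHPTPQADAKWYSWMKQHTYDEEHKIMCQHIEVLRPCISVRVQWRWYNRGFFYPYDIWHHRNCVFHSHKWGYEPSKIGIWYVNGMFYEGHDMIKP
>terl_synthetic_03 category=TerL synthetic
TANDRSMKKRSLMKTYPAKRFATAWAPHSCQQFLHRRTNRSCSKGNHPTPQQPAKWYSWMKQHTSDECHKIMCQHIEWLRPCISVRAMWRWYNRGFFYPKDIWHHRQHVFHYHKWGYEPEKIGAWISNIMFYEGHDMIKP
>terl_synthetic_04 category=TerL synthetic
TANDRSMKNRQLDKTDPWKRFATAWAPHYCVQFLFRITNRSCSKGNHPTPTADAKWYSWMKQHRSDECHKWMCQHIEVLPPCISVRVQWRWYNRGFFFPGDIWCHRQHVFHSHKWGYEPSKIGLHIVNIMFYEGHDMIPP
>terl_synthetic_05 category=TerL synthetic
TQNDRRMKWRQIDKTYPANRFATLVAPHYCVQFLHRPTNRSCSKGVHPTPTADAKWYSWMMQHTSDECHKIFCQHIEVLRPCISVRVQWRWYNRFFFIPYDIWHHTQHVFHSHKWGYRPSKIGLWIVNIMFYEGHDMIKP
>terl_synthetic_06 category=TerL synthetic
TPNDRSMKERQLDKTYPTKRFRIAWAPHYCVQFLHRIRNRSCSKGNHPTPQADPKWYSWMKQHTSDEWHKIMCQHIESLRPCISWYVQCRWYNRGFFYPYDIWHHRQHVFHSIKWGEEPSKIGLWMVNIAFYEGHMMITP
>terl_synthetic_07 category=TerL synthetic
TANDRFMKKRQLDKTYPAKDFATAWAPHYCVQFLHRITNRSCSKGNHPTPQAAAKWYSWMKQHTSDECHKIMCQHIEVLRPCISVRVQWRCYNRGFFYPYDIWHHRQAVFHSHKWGYEPSCIGLWIRNIMFYIKHDMIKP
>terl_synthetic_08 category=TerL synthetic
TANDRHMKKRQLDKTYTAKRFATAWAPHYCVQFLHRITNRACSKGNHPTPQAWAKWYSWKKQHTSDECHRIMCQHIEVLRKCILVVVQWRWYMRGFFYPGDIWHHRQHVFHSHKWGYEPSKIGLWIVNIMFYEGHDMIKP
>terl_synthetic_09 category=TerL synthetic
TANDRSMKKRQLDKTYPAKRFKEAWAPHYSVQFLHRITNRSCSKGNHPTPQAIAKEYMWHKQETSDHCHKIMCQHIEVLRPVISVRQQWRWYNRGFFYPWKIWHIRQHVFHEHKWGYEPSKICLWIVNIMFYEGHDMIKP
>terl_synthetic_10 category=TerL synthetic
TANDRSRKKWQLDKTYPAHRFATAWAPHYCVQFLHRITTNSCSKGNHPTPQAHAHWYSWMKQHTSDECHKIDCQHWEQLRPCISVLVQWRWYNRGFFYPYDDWHHRQHVFMSVKWGYVPSKIGLWPVNIMFYEGHDMIKP
>terl_synthetic_11 category=TerL synthetic
TANDRKMRKRILDKTYPAKRFATAWAPHYCVQQLHRITNRHCVKGNHATPEADAKWYSQMKKHTSDECHKIMCQHIEVLRPCISVRPQWRWYNRGFFYPYDIWHHRQHGFHSHKWGYEPSKIGWWIVNIRHYEGHDMIKP
>terl_synthetic_12 category=TerL synthetic
TANDRSMKKRQLDKTYPAKRFATARAPHYCPQFLHRCTNRSCSIRNHLTPMADAHWKSWMKQHTSDYCHKIMCIHIEVLRPCISVRVQWRTYPRGFFDPYDILHHRQHVFHSHKWGYESSKIGLLIVNIMFYQQHDMIKP
>terl_synthetic_13 category=TerL synthetic
TANDRSMKKRQLDKTYPAKSFATAWAPLVCVQFLHRITNRTCSKGNKPTPQADAKWYSWMKQHTSDECHKILCQHIEILRICISVRVQWRWYNRGFFYPYDIWHHRQHVFHSHKWGYEPSKIGLWIVNIMFYECHDMIKP
>terl_synthetic_14 category=TerL synthetic
TANDRSMKKRRLDKTYPAKRFATAWAPHYCVQTLHSITNRHCSNGNLPTPQADAKWESWMKQHYSDECLKIMCAHIEVLRPSISHRVQWRWYNRGFFYPYDICHHRNNAFHSHRWGYEFSKIGLWIVNIMFYEGHIMIKP
>terl_synthetic_15 category=TerL synthetic
TAFDRSMKKRQLDLTYPAERFARADAPEYCVQFLHRITNRSCSKGHHPTPQADAKWYQWMKQHTSDECHKIMCQHIEVLRPCISVRFQWRWYNRNFFYPYDIWHHRQHVFHSYKPGYEPSKIGLWIVNIMFYEGHDMIKP
>terl_synthetic_16 category=TerL synthetic
TATDRSMKSRQLDKTYQAKRFATAWAPHYCVQTLHRITNRSCQKGNAPTPQGDAKWYSWMKQHDSDKCHKIMCQHIEVLHPCIGVRVQWRWYCRGFFYPYDIWHHRQHVFHSHKWGYEPSKIGLWIVNIGFYEGHDMPMP
>terl_synthetic_17 category=TerL synthetic
WANDRSMKKRQLDKTYPAKRFCTAWAPHYCVQFTHRITVRSCSKGKCPTPYADRKWYFWDKQHTSDECHKVMCQHIEVLRPCISVRVQWRWYNRRFFYPYDIWHHRQHVFHSHKWGLEPSKIGLWIVNIMFYEGHDMMKP
>terl_synthetic_18 category=TerL synthetic
TANDRSMKKGQLDKTYPAKRFATAWAPHYCVQFDHRITNRSCSKGNHPDQQADAKWSSWPKQHTSDGCHFIMCWHIEILRPCISVRVQWRWYNRGFKYPYDIWHHRQHVFHCRKWCYEPSKSGLWIVNIMFYEGHDMIKV
>terl_synthetic_19 category=TerL synthetic
TANSRSMKKRQLDKTYPHKRFATAWAPHYCVQALHRETHRSCSKGNFPTPQADAKWYSWMKQHTSDECHKIMCCHIEVLRPCISVRVQWRAYNRGFFYPSDIWHHRQHVFHMGKWGYEPSKIGLWIVNIFFYEGHDMIKP
>terl_synthetic_20 category=TerL synthetic
TANDRQMKKLQPDKFYPAKRFATEEAPHYCVWFLHRIWNRSCSKGNHPTPQADACWYSWMKQHTSDECHKIMCQHICVEMPCISVRVQWRWENRGFFYPYDIWHHRQHVFHSHKWGYEPSKIGLWIVHIMFYEGHDMIKP
>terl_synthetic_21 category=TerL synthetic
TANDRIMKKRQLDKNYHAKRFATAWAPYYCVYFLHRITNRSCSKKNHPTPQADAEWYSWMKQHTSDECHKIMCQRIEVLRPCIGVRVQWRWYNRNFFYPWDIWHHRQVVFHSHKWGYEPSKIGLFNVNIQFYEGHDMIKP
>terl_synthetic_22 category=TerL synthetic
TANDRSMKKRQLDKTYPQKRFATAWAPHYCVPFLHRITNRSCSKTMHPTPQADAKWSSWMKKHGSDECHKIMTQHIEVFRPCISVRVQWRWYNRGFFMPYYIWFHRQHVFHSHKWGYPPSKCGLWIVNIMFYELHDMIKP
>terl_synthetic_23 category=TerL synthetic
TANDRSMKKHQLDGTYNAKRFATAWAPHKCVQFLHRITNSSHSKGNAPTPQADAKGYLWMKQHDSDDCDKIMCQHIEVLDPCISVRVQWRWYNRGFFYPYDIWHFRGHVFHSHKWGYEISKIGLWIVWIMFYEGHDQIKS
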